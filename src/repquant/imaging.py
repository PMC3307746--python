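"""Negative-control-calibrated multi-channel immunofluorescence quantification.

Each stained field carries one greyscale image per marker channel (MHCII,
SIRPa, CD11R1, CD16, ...) plus a matched negative-control field processed in
conjunction with the sample.  Background staining levels (thresholds) are
read off the negative controls per channel; pixels strictly above threshold
are positive, and outcomes are proportions of positive pixels over the whole
image.  MHCII+ pixels (antigen-presenting cells) are partitioned into the 8
Boolean combinations of SIRPa/CD11R1/CD16; the triple-negative combination is
capillary endothelium, which constitutively expresses MHCII, and is reported
separately from the myeloid subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
import tifffile

from .repertoire import GLMTable
from .spectra import SampleMeta

__all__ = [
    "APC_MARKERS",
    "MHCII",
    "SUBSET_LABELS",
    "ENDOTHELIAL_SUBSET",
    "FieldSet",
    "estimate_thresholds",
    "binarise",
    "proportion_positive",
    "subset_partition",
    "quantify_field",
    "quantify_cohort",
    "area_anova",
    "read_manifest",
]

MHCII = "MHCII"
APC_MARKERS = ("SIRPa", "CD11R1", "CD16")


def subset_label(flags: Sequence[bool]) -> str:
    return "".join(
        f"{m}{'+' if f else '-'}" for m, f in zip(APC_MARKERS, flags)
    )


#: the 8 Boolean combinations of SIRPa/CD11R1/CD16 within MHCII+ pixels
SUBSET_LABELS = tuple(
    subset_label(flags) for flags in product([True, False], repeat=3)
)
#: MHCII+ triple-negative pixels: constitutive endothelial MHCII
ENDOTHELIAL_SUBSET = subset_label((False, False, False))


@dataclass
class FieldSet:
    """One registered multi-channel field plus its matched negative control."""

    field_id: str
    channels: dict[str, np.ndarray]
    negative_controls: dict[str, np.ndarray]
    sample: SampleMeta | None = None

    def __post_init__(self) -> None:
        shapes = {m: a.shape for m, a in self.channels.items()}
        shapes.update({f"nc:{m}": a.shape for m, a in self.negative_controls.items()})
        if len(set(shapes.values())) > 1:
            raise ValueError(f"field {self.field_id}: channel shapes differ: {shapes}")
        for m, a in self.channels.items():
            arr = np.asarray(a)
            if arr.ndim != 2:
                raise ValueError(f"field {self.field_id}: channel {m} is not 2-D")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(
                    f"field {self.field_id}: channel {m} has negative or non-finite pixels"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def estimate_thresholds(
    fieldset: FieldSet, percentile: float = 100.0
) -> dict[str, float]:
    """Per-channel background thresholds from the matched negative control.

    The threshold is the given percentile of the negative-control intensity
    distribution for that channel; the default (100th percentile, i.e. the
    maximum) is the strictest reading of "background level" — no negative-
    control pixel exceeds its own threshold.  Lower percentiles (e.g. 99.5)
    are robust to hot pixels.
    """
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    out: dict[str, float] = {}
    for marker in fieldset.channels:
        if marker not in fieldset.negative_controls:
            raise ValueError(
                f"field {fieldset.field_id}: no negative control for channel {marker!r}"
            )
        out[marker] = float(
            np.percentile(fieldset.negative_controls[marker], percentile)
        )
    return out


def binarise(
    fieldset: FieldSet, thresholds: Mapping[str, float]
) -> dict[str, np.ndarray]:
    """Positive-pixel masks: intensity strictly above the channel threshold."""
    masks: dict[str, np.ndarray] = {}
    for marker, img in fieldset.channels.items():
        if marker not in thresholds:
            raise ValueError(f"no threshold supplied for channel {marker!r}")
        masks[marker] = np.asarray(img) > thresholds[marker]
    return masks


def proportion_positive(mask: np.ndarray) -> float:
    """Positive pixels as a proportion of the whole image (no ROI masking)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty image")
    return float(np.count_nonzero(mask)) / mask.size


def subset_partition(masks: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Partition MHCII+ pixels by the 8 SIRPa/CD11R1/CD16 Boolean combinations.

    Every MHCII+ pixel lands in exactly one combination, so the 8 counts sum
    to the MHCII+ count and the SIRPa+ and SIRPa- shares of MHCII sum to 1.
    Proportions (``area_*``) are over the whole image; shares (``share_*``)
    are fractions of the MHCII+ area.  The triple-negative combination is
    endothelial MHCII.
    """
    needed = (MHCII,) + APC_MARKERS
    missing = [m for m in needed if m not in masks]
    if missing:
        raise ValueError(f"subset_partition: missing mask(s) {missing}")
    shapes = {m: np.asarray(masks[m]).shape for m in needed}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"subset_partition: unregistered mask shapes {shapes}")
    mhc = np.asarray(masks[MHCII], dtype=bool)
    n_pixels = mhc.size
    mhc_count = int(np.count_nonzero(mhc))
    out: dict[str, float] = {
        "n_pixels": n_pixels,
        "count_MHCII": mhc_count,
        "area_MHCII": mhc_count / n_pixels,
    }
    sirpa_pos_count = 0
    for flags in product([True, False], repeat=3):
        sel = mhc.copy()
        for m, f in zip(APC_MARKERS, flags):
            sel &= np.asarray(masks[m], dtype=bool) if f else ~np.asarray(
                masks[m], dtype=bool
            )
        c = int(np.count_nonzero(sel))
        lab = subset_label(flags)
        out[f"count_{lab}"] = c
        out[f"area_{lab}"] = c / n_pixels
        out[f"share_{lab}"] = c / mhc_count if mhc_count else 0.0
        if flags[0]:
            sirpa_pos_count += c
    out["share_SIRPa_pos"] = sirpa_pos_count / mhc_count if mhc_count else 0.0
    out["share_SIRPa_neg"] = (
        (mhc_count - sirpa_pos_count) / mhc_count if mhc_count else 0.0
    )
    out["area_endothelial"] = out[f"area_{ENDOTHELIAL_SUBSET}"]
    return out


def quantify_field(
    fieldset: FieldSet,
    thresholds: Mapping[str, float] | None = None,
    percentile: float = 100.0,
) -> dict[str, float]:
    """Threshold, binarise and partition one field; returns one table row."""
    if thresholds is None:
        thresholds = estimate_thresholds(fieldset, percentile=percentile)
    masks = binarise(fieldset, thresholds)
    row: dict[str, float] = {"field_id": fieldset.field_id}
    if fieldset.sample is not None:
        row.update(
            animal_id=fieldset.sample.animal_id,
            status=fieldset.sample.status,
            tissue=fieldset.sample.tissue,
            age_days=fieldset.sample.age_days,
        )
    for marker, mask in masks.items():
        row[f"prop_{marker}"] = proportion_positive(mask)
    if all(m in masks for m in (MHCII,) + APC_MARKERS):
        row.update(subset_partition(masks))
    return row


def quantify_cohort(
    fieldsets: Sequence[FieldSet], percentile: float = 100.0
) -> pd.DataFrame:
    """Quantify every field; one row per field (the SubsetAreaTable)."""
    if not fieldsets:
        raise ValueError("no fields supplied")
    return pd.DataFrame([quantify_field(f, percentile=percentile) for f in fieldsets])


# ---------------------------------------------------------------------------
# group-effect ANOVA on proportion-positive areas

def area_anova(
    table: pd.DataFrame,
    outcome: str,
    family_alpha: float = 0.05,
    n_tests: int = 8,
    unit: str = "animal",
    animal_as_numeric_covariate: bool = False,
) -> GLMTable:
    """ANOVA of a proportion-positive outcome on treatment (status) and age.

    The default unit of analysis is the per-animal mean over its fields (the
    study's n refers to animals); per-field rows are accepted and aggregated.
    With ``unit="field"`` each field is a row and the animal enters as an
    additive categorical block (diagnostic only: with animals nested in
    treatment groups the block absorbs the between-animal variance the
    treatment test should be judged against).  Type-III sums of squares with
    sum-to-zero contrasts; the interaction is dropped with a warning when a
    design cell has no animals.  Per-test alpha is ``family_alpha/n_tests``.
    """
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} not in table")
    needed = {"animal_id", "status", "age_days"}
    if missing := needed - set(table.columns):
        raise ValueError(f"area table missing columns {sorted(missing)}")
    df = table[["animal_id", "status", "age_days", outcome]].rename(
        columns={outcome: "y"}
    )
    if unit == "animal":
        df = (
            df.groupby(["animal_id", "status", "age_days"], as_index=False)["y"]
            .mean()
        )
    elif unit != "field":
        raise ValueError(f"unit must be 'animal' or 'field', got {unit!r}")

    terms = []
    if df["status"].nunique() >= 2:
        terms.append("C(status, Sum)")
    else:
        warnings.warn("area_anova: single status level; treatment term dropped",
                      stacklevel=2)
    if df["age_days"].nunique() >= 2:
        terms.append("C(age_days, Sum)")
    else:
        warnings.warn("area_anova: single age level; age term dropped", stacklevel=2)
    if not terms:
        raise ValueError("neither treatment nor age has >=2 levels")

    with_interaction = len(terms) == 2
    if with_interaction:
        cells = df.groupby(["status", "age_days"]).size()
        full = df["status"].nunique() * df["age_days"].nunique()
        if len(cells) < full:
            warnings.warn(
                "area_anova: empty design cell(s); interaction dropped", stacklevel=2
            )
            with_interaction = False
    rhs = " + ".join(terms)
    if with_interaction:
        rhs += " + C(status, Sum):C(age_days, Sum)"
    if unit == "field":
        if animal_as_numeric_covariate:
            df = df.assign(animal_code=pd.factorize(df["animal_id"])[0].astype(float))
            rhs += " + animal_code"
        else:
            rhs += " + C(animal_id)"

    res = smf.ols(f"y ~ {rhs}", data=df).fit()
    aov = sm.stats.anova_lm(res, typ=3)
    row: dict[str, float] = {
        "outcome": outcome, "model_F": res.fvalue, "model_p": res.f_pvalue,
    }
    mapping = {
        "treatment": "C(status, Sum)",
        "age": "C(age_days, Sum)",
        "interaction": "C(status, Sum):C(age_days, Sum)",
    }
    for name, key in mapping.items():
        if key in aov.index:
            row[f"{name}_F"] = aov.loc[key, "F"]
            row[f"{name}_p"] = aov.loc[key, "PR(>F)"]
        else:
            row[f"{name}_F"] = np.nan
            row[f"{name}_p"] = np.nan
    out = pd.DataFrame([row]).set_index("outcome")
    return GLMTable(table=out, family_alpha=family_alpha, n_tests=n_tests)


# ---------------------------------------------------------------------------
# manifest I/O

MANIFEST_COLUMNS = (
    "field_id", "animal_id", "status", "tissue", "age_days", "marker", "role", "path",
)


def read_manifest(manifest_path: str | Path) -> list[FieldSet]:
    """Load a cohort of fields from a manifest CSV plus per-channel TIFFs.

    The manifest has one row per (field, channel, role) with ``role`` either
    ``stain`` or ``negative``; paths are relative to the manifest location.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    man = pd.read_csv(manifest_path)
    if missing := set(MANIFEST_COLUMNS) - set(man.columns):
        raise ValueError(f"manifest {manifest_path}: missing columns {sorted(missing)}")
    base = manifest_path.parent
    fields: list[FieldSet] = []
    for field_id, sub in man.groupby("field_id", sort=True):
        channels: dict[str, np.ndarray] = {}
        ncs: dict[str, np.ndarray] = {}
        first = sub.iloc[0]
        sample = SampleMeta(
            animal_id=str(first["animal_id"]),
            status=str(first["status"]),
            tissue=str(first["tissue"]),
            age_days=int(first["age_days"]),
        )
        for rec in sub.itertuples():
            img = tifffile.imread(base / str(rec.path)).astype(np.float64)
            if rec.role == "stain":
                channels[str(rec.marker)] = img
            elif rec.role == "negative":
                ncs[str(rec.marker)] = img
            else:
                raise ValueError(
                    f"manifest {manifest_path}: field {field_id}: bad role {rec.role!r}"
                )
        fields.append(
            FieldSet(
                field_id=str(field_id),
                channels=channels,
                negative_controls=ncs,
                sample=sample,
            )
        )
    return fields
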
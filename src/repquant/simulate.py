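"""Synthetic spectratype and immunofluorescence data with known ground truth.

The generator emulates the statistical structure the analyses assume:

* **Spectratypes** — per sample x TRBV group, a CDR3-length bin-probability
  vector is drawn from a Dirichlet whose mean is a tissue-specific base
  profile and whose concentration is the tissue's clonality knob.  Spleen
  uses a high concentration around a discretised Gaussian profile (diverse,
  bell-shaped ladders); jejunal tissues use a low concentration around a
  sparsified profile with tissue-specific dominant bins (skewed, oligoclonal
  ladders from tissue-restricted clone recruitment).  Probabilities are
  scaled to rfu, placed on the 3-bp in-frame grid with bp jitter (clipped
  below the QC tolerance so true peaks always survive), and sub-70-rfu noise
  peaks are sprinkled in (always removed by default QC).
* **Image fields** — non-overlapping disc/ellipse "cells", each positive in
  exactly the channels of its assigned SIRPa/CD11R1/CD16 subset (all cells
  MHCII+), over Gaussian background; matched negative-control fields share
  the background distribution, so negative-control maxima are honest
  background thresholds.  Ground truth records exact per-subset pixel
  fractions.
* **Area tables** — animal-level subset areas drawn directly from the
  between-animal model (Normal with a stated CV), for fast Monte-Carlo
  calibration of the ANOVA layer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse

from .imaging import APC_MARKERS, MHCII, SUBSET_LABELS, FieldSet, subset_label
from .registry import TRBVRegistry, default_registry, save_registry
from .spectra import (
    DEFAULT_MIN_RFU,
    TISSUES,
    SampleMeta,
)

__all__ = [
    "SpectraSimConfig",
    "SpectraDataset",
    "simulate_spectra",
    "ImageSimConfig",
    "ImageDataset",
    "simulate_fields",
    "simulate_area_tables",
    "DEFAULT_SUBSET_MEANS",
]


# ---------------------------------------------------------------------------
# spectratype simulation

@dataclass(frozen=True)
class SpectraSimConfig:
    """Study-design and noise parameters for the spectratype generator.

    ``clonality`` is the Dirichlet concentration per tissue: high values give
    tight, Gaussian-like profiles (diverse repertoire), low values give
    oligoclonal draws dominated by few CDR3 lengths.  ``status_effect``
    injects a shared clone expansion into colonised samples so the GLM's
    power (not only its type-I error) is testable; it is off by default
    because the study design it emulates found no colonisation effect.
    """

    seed: int = 0
    n_animals_per_status: int = 4
    tissues: tuple[str, ...] = TISSUES
    age_days: int = 21
    clonality: Mapping[str, float] = field(
        default_factory=lambda: {
            "spleen": 60.0,
            "proximal_jejunum": 3.0,
            "distal_jejunum": 3.0,
        }
    )
    status_effect: bool = False
    status_effect_size: float = 0.35
    n_bins: int = 9
    rfu_scale: float = 5000.0
    noise_peak_rate: float = 3.0
    noise_rfu_bounds: tuple[float, float] = (10.0, 69.0)
    bp_jitter_sd: float = 0.15
    bp_jitter_max: float = 0.9
    spacing_bp: float = 3.0
    jejunum_temper: float = 0.3
    jejunum_sparsity: float = 0.4

    def validate(self) -> None:
        if self.n_animals_per_status < 1:
            raise ValueError("n_animals_per_status must be >= 1")
        if self.n_bins < 1 or self.n_bins % 2 == 0:
            raise ValueError("n_bins must be a positive odd integer")
        for t in self.tissues:
            if t not in self.clonality:
                raise ValueError(f"no clonality given for tissue {t!r}")
            if not self.clonality[t] > 0:
                raise ValueError(f"clonality for {t!r} must be > 0")
        if self.bp_jitter_sd < 0:
            raise ValueError("bp_jitter_sd must be >= 0")
        if not 0 < self.bp_jitter_max:
            raise ValueError("bp_jitter_max must be > 0")
        lo, hi = self.noise_rfu_bounds
        if not (0 <= lo <= hi):
            raise ValueError("noise_rfu_bounds must satisfy 0 <= lo <= hi")
        if hi >= DEFAULT_MIN_RFU:
            raise ValueError(
                f"noise peak heights must stay below the {DEFAULT_MIN_RFU} rfu QC "
                f"threshold, got upper bound {hi}"
            )
        if not 0 <= self.status_effect_size < 1:
            raise ValueError("status_effect_size must be in [0, 1)")


@dataclass
class SpectraDataset:
    """Simulated peak tables plus everything needed to recompute expectations."""

    peaks: pd.DataFrame
    metadata: dict[str, SampleMeta]
    registry: TRBVRegistry
    config: SpectraSimConfig
    #: (sample_id, group_id) -> true bin-probability vector (index k_min..k_max)
    true_profiles: dict[tuple[str, str], np.ndarray]
    #: (sample_id, group_id) -> emitted signal rfu per bin (before noise peaks)
    bin_heights: dict[tuple[str, str], np.ndarray]
    bin_indices: np.ndarray

    def expected_proportions(
        self, sample_id: str, group_id: str, min_rfu: float = DEFAULT_MIN_RFU
    ) -> dict[int, float] | None:
        """Proportions the QC pipeline should report: sub-threshold signal
        bins are rejected at QC, so the expectation renormalises the
        surviving bin heights."""
        h = self.bin_heights[(sample_id, group_id)]
        keep = h >= min_rfu
        total = h[keep].sum()
        if total <= 0:
            return None
        return {
            int(k): float(v / total)
            for k, v in zip(self.bin_indices[keep], h[keep])
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peaks.to_csv(outdir / "peaks.csv", index=False)
        pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "animal_id": m.animal_id,
                    "status": m.status,
                    "tissue": m.tissue,
                    "age_days": m.age_days,
                }
                for sid, m in self.metadata.items()
            ]
        ).to_csv(outdir / "metadata.csv", index=False)
        save_registry(self.registry, outdir / "registry.yaml")
        truth = {
            "config": dataclasses.asdict(self.config),
            "bin_indices": [int(k) for k in self.bin_indices],
            "samples": {
                f"{sid}::{gid}": {
                    "true_profile": [float(x) for x in p],
                    "bin_heights": [
                        float(x) for x in self.bin_heights[(sid, gid)]
                    ],
                }
                for (sid, gid), p in self.true_profiles.items()
            },
        }
        truth["config"]["clonality"] = dict(self.config.clonality)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def _gaussian_profile(n_bins: int) -> np.ndarray:
    k = np.arange(n_bins) - n_bins // 2
    sigma = n_bins / 6.0
    g = np.exp(-0.5 * (k / sigma) ** 2)
    return g / g.sum()


def simulate_spectra(
    config: SpectraSimConfig, registry: TRBVRegistry | None = None
) -> SpectraDataset:
    """Generate a cohort of spectratype peak tables with known ground truth."""
    config.validate()
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(config.seed)
    n_bins = config.n_bins
    half = n_bins // 2
    bin_indices = np.arange(-half, half + 1)
    gauss = _gaussian_profile(n_bins)

    # tissue-specific base profiles per group, shared by all animals of the run
    base: dict[tuple[str, str], np.ndarray] = {}
    for tissue in config.tissues:
        for gid in registry.group_ids:
            if tissue == "spleen":
                base[(tissue, gid)] = gauss
            else:
                w = rng.dirichlet(np.full(n_bins, config.jejunum_sparsity))
                b = (gauss**config.jejunum_temper) * (w + 1e-12)
                base[(tissue, gid)] = b / b.sum()

    # one shared "public clone" bin per group for the optional status effect
    effect_bin = {
        gid: int(rng.integers(0, n_bins)) for gid in registry.group_ids
    }

    animals = [("GF", f"GF{i + 1}") for i in range(config.n_animals_per_status)] + [
        ("colonised", f"CO{i + 1}") for i in range(config.n_animals_per_status)
    ]

    records: list[dict] = []
    metadata: dict[str, SampleMeta] = {}
    true_profiles: dict[tuple[str, str], np.ndarray] = {}
    bin_heights: dict[tuple[str, str], np.ndarray] = {}
    jitter_clip = min(config.bp_jitter_max, 0.9)
    for status, animal_id in animals:
        for tissue in config.tissues:
            meta = SampleMeta(
                animal_id=animal_id,
                status=status,
                tissue=tissue,
                age_days=config.age_days,
            )
            sid = meta.sample_id
            metadata[sid] = meta
            conc = config.clonality[tissue]
            for gid in registry.group_ids:
                group = registry[gid]
                p = rng.dirichlet(conc * base[(tissue, gid)] + 1e-6)
                if config.status_effect and status == "colonised":
                    e = config.status_effect_size
                    onehot = np.zeros(n_bins)
                    onehot[effect_bin[gid]] = 1.0
                    p = (1 - e) * p + e * onehot
                heights = p * config.rfu_scale
                true_profiles[(sid, gid)] = p
                bin_heights[(sid, gid)] = heights
                jitter = np.clip(
                    rng.normal(0.0, config.bp_jitter_sd, size=n_bins),
                    -jitter_clip,
                    jitter_clip,
                )
                sizes = group.anchor_bp + bin_indices * config.spacing_bp + jitter
                for s, h in zip(sizes, heights):
                    records.append(
                        {
                            "sample_id": sid,
                            "group_id": gid,
                            "size_bp": float(s),
                            "height_rfu": float(h),
                        }
                    )
                n_noise = rng.poisson(config.noise_peak_rate)
                lo, hi = group.range_bp
                for _ in range(n_noise):
                    records.append(
                        {
                            "sample_id": sid,
                            "group_id": gid,
                            "size_bp": float(rng.uniform(lo, hi)),
                            "height_rfu": float(rng.uniform(*config.noise_rfu_bounds)),
                        }
                    )
    peaks = pd.DataFrame.from_records(records).sort_values(
        ["sample_id", "group_id", "size_bp"], kind="mergesort", ignore_index=True
    )
    return SpectraDataset(
        peaks=peaks,
        metadata=metadata,
        registry=registry,
        config=config,
        true_profiles=true_profiles,
        bin_heights=bin_heights,
        bin_indices=bin_indices,
    )


# ---------------------------------------------------------------------------
# immunofluorescence field simulation

DEFAULT_CELLS_PER_SUBSET: dict[str, int] = {
    subset_label((True, False, False)): 4,
    subset_label((True, True, False)): 3,
    subset_label((True, True, True)): 2,
    subset_label((True, False, True)): 2,
    subset_label((False, True, False)): 3,
    subset_label((False, True, True)): 2,
    subset_label((False, False, True)): 2,
    subset_label((False, False, False)): 3,  # endothelial MHCII
}


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters for rendering synthetic multi-channel fields.

    Cells are non-overlapping ellipses; each is positive (signal intensity
    distribution) in MHCII plus the channels of its subset and background
    elsewhere.  The negative control shares the background distribution, so
    a maximum-of-negative-control threshold yields essentially zero false-
    positive area.  Intensities emulate a 16-bit camera.
    """

    seed: int = 0
    shape: tuple[int, int] = (160, 160)
    cells_per_subset: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS_PER_SUBSET)
    )
    radius_range: tuple[float, float] = (4.0, 8.0)
    aspect_range: tuple[float, float] = (0.6, 1.0)
    signal_mean: float = 30000.0
    signal_sd: float = 2000.0
    background_mean: float = 1200.0
    background_sd: float = 150.0
    n_fields_per_animal: int = 10
    n_animals_per_status: int = 3
    age_days: int = 5
    tissue: str = "proximal_jejunum"
    status_effect_subset: str | None = None
    status_effect_multiplier: float = 2.0
    max_fill: float = 0.4

    def validate(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("field shape too small")
        for lab, n in self.cells_per_subset.items():
            if lab not in SUBSET_LABELS:
                raise ValueError(f"unknown subset label {lab!r}")
            if n < 0:
                raise ValueError(f"cell count for {lab!r} must be >= 0")
        if self.background_mean < 0 or self.signal_mean < 0:
            raise ValueError("intensity means must be non-negative")
        if self.status_effect_subset is not None and (
            self.status_effect_subset not in SUBSET_LABELS
        ):
            raise ValueError(f"unknown subset {self.status_effect_subset!r}")
        # capacity: worst-case total cell area must fit the field
        r_max = self.radius_range[1]
        worst = sum(self.cells_per_subset.values()) * np.pi * r_max**2
        if self.status_effect_subset is not None:
            worst *= self.status_effect_multiplier
        if worst > self.max_fill * self.shape[0] * self.shape[1]:
            raise ValueError(
                "requested cell area exceeds field capacity "
                f"({worst:.0f} px > {self.max_fill:.0%} of {self.shape[0] * self.shape[1]} px)"
            )


@dataclass
class ImageDataset:
    """Simulated fields plus exact per-field ground-truth subset fractions."""

    fieldsets: list[FieldSet]
    truth: pd.DataFrame
    config: ImageSimConfig

    def write(self, outdir: str | Path) -> Path:
        """Write per-channel uint16 TIFFs, a manifest CSV and the truth CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for fs in self.fieldsets:
            meta = fs.sample
            for role, imgs in (("stain", fs.channels), ("negative", fs.negative_controls)):
                for marker, img in imgs.items():
                    fname = f"{fs.field_id}_{marker}_{role}.tif"
                    tifffile.imwrite(
                        outdir / fname,
                        np.clip(np.round(img), 0, 65535).astype(np.uint16),
                    )
                    rows.append(
                        {
                            "field_id": fs.field_id,
                            "animal_id": meta.animal_id,
                            "status": meta.status,
                            "tissue": meta.tissue,
                            "age_days": meta.age_days,
                            "marker": marker,
                            "role": role,
                            "path": fname,
                        }
                    )
        pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
        self.truth.to_csv(outdir / "ground_truth.csv", index=False)
        return outdir / "manifest.csv"


def _place_cells(
    rng: np.random.Generator, config: ImageSimConfig, counts: Mapping[str, int]
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Rejection-sample non-overlapping ellipses; returns (subset, rr, cc)."""
    h, w = config.shape
    occupied = np.zeros(config.shape, dtype=bool)
    cells = []
    for lab in SUBSET_LABELS:
        for _ in range(int(counts.get(lab, 0))):
            for _attempt in range(500):
                r_rad = rng.uniform(*config.radius_range)
                c_rad = r_rad * rng.uniform(*config.aspect_range)
                rot = rng.uniform(0, np.pi)
                cy = rng.uniform(r_rad + 1, h - r_rad - 1)
                cx = rng.uniform(r_rad + 1, w - r_rad - 1)
                rr, cc = draw_ellipse(cy, cx, r_rad, c_rad, rotation=rot)
                if (
                    rr.min() < 0 or rr.max() >= h or cc.min() < 0 or cc.max() >= w
                    or occupied[rr, cc].any()
                ):
                    continue
                occupied[rr, cc] = True
                cells.append((lab, rr, cc))
                break
            else:
                raise RuntimeError(
                    "cell placement failed after 500 attempts; field too crowded"
                )
    return cells


def simulate_fields(config: ImageSimConfig) -> ImageDataset:
    """Render a cohort of synthetic multi-channel fields with ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = (MHCII,) + APC_MARKERS
    n_px = config.shape[0] * config.shape[1]
    animals = [
        ("GF", f"GF{i + 1}") for i in range(config.n_animals_per_status)
    ] + [("colonised", f"CO{i + 1}") for i in range(config.n_animals_per_status)]

    fieldsets: list[FieldSet] = []
    truth_rows: list[dict] = []
    for status, animal_id in animals:
        counts = dict(config.cells_per_subset)
        if config.status_effect_subset is not None and status == "colonised":
            counts[config.status_effect_subset] = int(
                round(counts[config.status_effect_subset] * config.status_effect_multiplier)
            )
        meta = SampleMeta(
            animal_id=animal_id,
            status=status,
            tissue=config.tissue,
            age_days=config.age_days,
        )
        for f in range(config.n_fields_per_animal):
            field_id = f"{animal_id}_f{f + 1:02d}"
            cells = _place_cells(rng, config, counts)
            channels = {
                m: np.clip(
                    rng.normal(config.background_mean, config.background_sd, config.shape),
                    0,
                    None,
                )
                for m in markers
            }
            ncs = {
                m: np.clip(
                    rng.normal(config.background_mean, config.background_sd, config.shape),
                    0,
                    None,
                )
                for m in markers
            }
            subset_px = {lab: 0 for lab in SUBSET_LABELS}
            marker_px = {m: 0 for m in markers}
            for lab, rr, cc in cells:
                pos = {m: f"{m}+" in lab for m in APC_MARKERS}
                subset_px[lab] += rr.size
                marker_px[MHCII] += rr.size
                sig_markers = [MHCII] + [m for m in APC_MARKERS if pos[m]]
                for m in APC_MARKERS:
                    if pos[m]:
                        marker_px[m] += rr.size
                for m in sig_markers:
                    channels[m][rr, cc] = np.clip(
                        rng.normal(config.signal_mean, config.signal_sd, rr.size),
                        0,
                        None,
                    )
            fieldsets.append(
                FieldSet(
                    field_id=field_id,
                    channels=channels,
                    negative_controls=ncs,
                    sample=meta,
                )
            )
            row = {
                "field_id": field_id,
                "animal_id": animal_id,
                "status": status,
                "age_days": config.age_days,
                "n_pixels": n_px,
            }
            for lab in SUBSET_LABELS:
                row[f"true_area_{lab}"] = subset_px[lab] / n_px
            for m in markers:
                row[f"true_prop_{m}"] = marker_px[m] / n_px
            truth_rows.append(row)
    return ImageDataset(
        fieldsets=fieldsets, truth=pd.DataFrame(truth_rows), config=config
    )


# ---------------------------------------------------------------------------
# parametric area tables for ANOVA Monte-Carlo

DEFAULT_SUBSET_MEANS: dict[str, float] = {
    subset_label((True, False, False)): 0.030,
    subset_label((True, True, False)): 0.020,
    subset_label((True, True, True)): 0.012,
    subset_label((True, False, True)): 0.010,
    subset_label((False, True, False)): 0.018,
    subset_label((False, True, True)): 0.012,
    subset_label((False, False, True)): 0.008,
    subset_label((False, False, False)): 0.025,
}


def simulate_area_tables(
    seed: int,
    n_per_status: int = 3,
    subset_means: Mapping[str, float] | None = None,
    between_animal_cv: float = 0.2,
    within_animal_cv: float = 0.05,
    n_fields: int = 10,
    effect_subset: str | None = None,
    effect_multiplier: float = 2.0,
    age_days: int = 5,
) -> pd.DataFrame:
    """Draw a per-field SubsetAreaTable directly from the between-animal model.

    Each animal's true subset area is Normal(group mean, CV x group mean),
    truncated at 0; its fields add Normal within-animal noise.  When
    ``effect_subset`` is set, colonised group means for that subset are
    multiplied by ``effect_multiplier`` and all other subsets are untouched.
    """
    if subset_means is None:
        subset_means = DEFAULT_SUBSET_MEANS
    rng = np.random.default_rng(seed)
    rows = []
    for status in ("GF", "colonised"):
        for i in range(n_per_status):
            animal_id = f"{'GF' if status == 'GF' else 'CO'}{i + 1}"
            animal_true = {}
            for lab, mu in subset_means.items():
                if effect_subset == lab and status == "colonised":
                    mu = mu * effect_multiplier
                animal_true[lab] = max(
                    rng.normal(mu, between_animal_cv * mu), 0.0
                )
            for f in range(n_fields):
                row = {
                    "animal_id": animal_id,
                    "status": status,
                    "age_days": age_days,
                    "field_id": f"{animal_id}_f{f + 1:02d}",
                }
                for lab, mu_a in animal_true.items():
                    row[f"area_{lab}"] = max(
                        rng.normal(mu_a, within_animal_cv * subset_means[lab]), 0.0
                    )
                rows.append(row)
    return pd.DataFrame(rows)
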
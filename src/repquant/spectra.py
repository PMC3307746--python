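"""CDR3 spectratype peak QC, binning, standardisation and matrix assembly.

A spectratype is the distribution of PCR-product fragment lengths (CDR3
lengths) within one TRBV group for one tissue sample.  Raw electropherogram
peak tables are quality-controlled with two rules — peaks below 70 rfu are
indistinguishable from background fluorescence and peaks more than 1 bp from
the nearest expected in-frame size are off-ladder artefacts — then assigned
to 3-bp CDR3-length bins, standardised to proportions of the total retained
signal, and assembled into the samples x (group, bin) repertoire matrix used
for clustering and ordination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import TRBVGroup, TRBVRegistry

__all__ = [
    "STATUSES",
    "TISSUES",
    "AGES",
    "RawPeak",
    "SampleMeta",
    "Spectratype",
    "RepertoireMatrix",
    "filter_peaks",
    "assign_bins",
    "standardise",
    "build_matrix",
    "process_peak_table",
    "read_peak_table",
    "read_sample_metadata",
]

STATUSES = ("GF", "colonised")
TISSUES = ("spleen", "proximal_jejunum", "distal_jejunum")
AGES = (0, 5, 21)

DEFAULT_MIN_RFU = 70.0
DEFAULT_BP_TOLERANCE = 1.0
DEFAULT_SPACING_BP = 3.0


@dataclass(frozen=True)
class RawPeak:
    """A single called electropherogram peak."""

    size_bp: float
    height_rfu: float

    def __post_init__(self) -> None:
        if not self.size_bp > 0:
            raise ValueError(f"size_bp must be positive, got {self.size_bp}")
        if self.height_rfu < 0:
            raise ValueError(f"height_rfu must be non-negative, got {self.height_rfu}")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one tissue sample from one animal."""

    animal_id: str
    status: str
    tissue: str
    age_days: int

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status {self.status!r} not in {STATUSES}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue {self.tissue!r} not in {TISSUES}")
        if int(self.age_days) not in AGES:
            raise ValueError(f"age_days {self.age_days!r} not in {AGES}")
        object.__setattr__(self, "age_days", int(self.age_days))

    @property
    def sample_id(self) -> str:
        return f"{self.animal_id}|{self.tissue}"


@dataclass(frozen=True)
class Spectratype:
    """Standardised CDR3-length profile for one sample x TRBV group.

    ``bins`` maps bin index (0 at the group anchor, steps of one in-frame
    3-bp class) to the proportion of total retained peak signal.
    """

    sample: SampleMeta
    group_id: str
    bins: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.bins:
            vals = np.fromiter(self.bins.values(), dtype=float)
            if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
                raise ValueError("spectratype proportions must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"spectratype proportions must sum to 1, got {vals.sum():.12f}"
                )


def _nearest_bin(size_bp: float, group: TRBVGroup, spacing_bp: float) -> int:
    """Index of the in-range grid size nearest ``size_bp``; ties -> lower index."""
    k_min, k_max = group.bin_span(spacing_bp)
    kf = (size_bp - group.anchor_bp) / spacing_bp
    k = math.ceil(kf - 0.5)  # round-half-down: equidistant peaks take the lower bin
    return min(max(k, k_min), k_max)


def filter_peaks(
    peaks: Sequence[RawPeak],
    group: TRBVGroup,
    min_rfu: float = DEFAULT_MIN_RFU,
    bp_tolerance: float = DEFAULT_BP_TOLERANCE,
    spacing_bp: float = DEFAULT_SPACING_BP,
) -> list[RawPeak]:
    """Apply the two peak-validation rules; order is preserved.

    A peak is retained iff its height is at least ``min_rfu`` (heights below
    70 rfu are not differentiable from background fluorescence; exactly 70 is
    accepted), its size lies within the group's anticipated bp range, and it
    is no more than ``bp_tolerance`` bp from the nearest expected in-frame
    size on the group's grid.
    """
    k_min, k_max = group.bin_span(spacing_bp)
    if k_max < k_min:
        raise ValueError(
            f"group {group.group_id}: expected-size grid is empty for spacing {spacing_bp}"
        )
    lo, hi = group.range_bp
    kept = []
    for p in peaks:
        if p.height_rfu < min_rfu:
            continue
        if not (lo <= p.size_bp <= hi):
            continue
        k = _nearest_bin(p.size_bp, group, spacing_bp)
        expected = group.anchor_bp + k * spacing_bp
        if abs(p.size_bp - expected) > bp_tolerance:
            continue
        kept.append(p)
    return kept


def assign_bins(
    peaks: Sequence[RawPeak],
    group: TRBVGroup,
    spacing_bp: float = DEFAULT_SPACING_BP,
) -> dict[int, float]:
    """Map accepted peaks to CDR3-length bins, summing co-binned heights.

    Bin index k corresponds to expected size ``anchor + k*spacing``; a peak
    exactly midway between two grid sizes goes to the lower index.  The total
    height is conserved.
    """
    bins: dict[int, float] = {}
    for p in peaks:
        k = _nearest_bin(p.size_bp, group, spacing_bp)
        bins[k] = bins.get(k, 0.0) + p.height_rfu
    return dict(sorted(bins.items()))


def standardise(bins: Mapping[int, float]) -> dict[int, float] | None:
    """Convert bin heights to proportions of the total spectratype signal.

    Returns ``None`` for an empty or all-zero input: such a spectratype
    failed QC entirely and is excluded from the matrix rather than imputed.
    """
    total = math.fsum(bins.values())
    if total <= 0.0:
        return None
    return {k: v / total for k, v in sorted(bins.items())}


@dataclass
class RepertoireMatrix:
    """Samples x (group, CDR3-bin) proportion matrix plus sample metadata.

    ``values`` is indexed by ``sample_id`` with a two-level column index
    ``(group_id, bin)``; entries for unobserved bins are 0, so each row's
    slice over one group's bins sums to 1, or to 0 if that group failed QC
    for that sample.  ``meta`` carries animal_id/status/tissue/age_days per
    row, aligned on the same index.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    qc_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same sample index")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def group_slice(self, group_id: str) -> pd.DataFrame:
        return self.values.loc[:, group_id]

    def write(self, values_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the matrix (two header rows: group_id, bin) and metadata CSVs."""
        # %.17g guarantees the proportions survive the text round-trip bit-exactly
        self.values.to_csv(values_path, float_format="%.17g")
        if meta_path is not None:
            self.meta.to_csv(meta_path)

    @classmethod
    def read(cls, values_path: str | Path, meta_path: str | Path) -> "RepertoireMatrix":
        values = pd.read_csv(
            values_path, header=[0, 1], index_col=0, float_precision="round_trip"
        )
        values.columns = pd.MultiIndex.from_tuples(
            [(g, int(b)) for g, b in values.columns], names=["group_id", "bin"]
        )
        meta = pd.read_csv(meta_path, index_col=0)
        return cls(values=values, meta=meta)


def build_matrix(spectratypes: Iterable[Spectratype]) -> RepertoireMatrix:
    """Assemble standardised spectratypes into one cross-sample matrix.

    Columns are the union of observed (group, bin) pairs sorted by
    (group_id, bin); rows are sorted by (animal_id, tissue).  A duplicate
    (sample, group) pair is an error.
    """
    specs = list(spectratypes)
    if not specs:
        raise ValueError("no spectratypes supplied")
    seen: set[tuple[str, str]] = set()
    rows: dict[str, dict[tuple[str, int], float]] = {}
    metas: dict[str, SampleMeta] = {}
    for s in specs:
        key = (s.sample.sample_id, s.group_id)
        if key in seen:
            raise ValueError(
                f"duplicate spectratype for sample {key[0]!r}, group {key[1]!r}"
            )
        seen.add(key)
        row = rows.setdefault(s.sample.sample_id, {})
        metas[s.sample.sample_id] = s.sample
        for b, p in s.bins.items():
            row[(s.group_id, int(b))] = p

    columns = sorted({c for row in rows.values() for c in row})
    order = sorted(metas, key=lambda sid: (metas[sid].animal_id, metas[sid].tissue))
    data = np.zeros((len(order), len(columns)))
    for i, sid in enumerate(order):
        for j, col in enumerate(columns):
            data[i, j] = rows[sid].get(col, 0.0)
    values = pd.DataFrame(
        data,
        index=pd.Index(order, name="sample_id"),
        columns=pd.MultiIndex.from_tuples(columns, names=["group_id", "bin"]),
    )
    meta = pd.DataFrame(
        {
            "animal_id": [metas[s].animal_id for s in order],
            "status": [metas[s].status for s in order],
            "tissue": [metas[s].tissue for s in order],
            "age_days": [metas[s].age_days for s in order],
        },
        index=values.index,
    )
    return RepertoireMatrix(values=values, meta=meta)


# ---------------------------------------------------------------------------
# delimited-text I/O and the end-to-end peak-table pipeline

PEAK_COLUMNS = ("sample_id", "group_id", "size_bp", "height_rfu")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a peak table CSV/TSV with columns sample_id, group_id, size_bp, height_rfu."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peak table not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path}: missing columns {sorted(missing)}")
    return df


def read_sample_metadata(path: str | Path) -> dict[str, SampleMeta]:
    """Read sample metadata CSV (sample_id, animal_id, status, tissue, age_days)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample metadata not found: {path}")
    df = pd.read_csv(path)
    needed = {"sample_id", "animal_id", "status", "tissue", "age_days"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    out: dict[str, SampleMeta] = {}
    for rec in df.to_dict("records"):
        out[str(rec["sample_id"])] = SampleMeta(
            animal_id=str(rec["animal_id"]),
            status=str(rec["status"]),
            tissue=str(rec["tissue"]),
            age_days=int(rec["age_days"]),
        )
    return out


def process_peak_table(
    peaks: pd.DataFrame,
    registry: TRBVRegistry,
    metadata: Mapping[str, SampleMeta],
    min_rfu: float = DEFAULT_MIN_RFU,
    bp_tolerance: float = DEFAULT_BP_TOLERANCE,
    spacing_bp: float = DEFAULT_SPACING_BP,
) -> RepertoireMatrix:
    """Run QC -> binning -> standardisation over a raw peak table.

    Spectratypes whose peaks are all rejected are recorded in the matrix's
    ``qc_log`` and dropped (their group slice is all-zero for that sample).
    """
    qc_log: list[str] = []
    specs: list[Spectratype] = []
    for (sample_id, group_id), sub in peaks.groupby(["sample_id", "group_id"], sort=True):
        sample_id = str(sample_id)
        group_id = str(group_id)
        if sample_id not in metadata:
            raise ValueError(f"peak table references unknown sample_id {sample_id!r}")
        group = registry[group_id]
        raw = [
            RawPeak(size_bp=float(r.size_bp), height_rfu=float(r.height_rfu))
            for r in sub.itertuples()
        ]
        kept = filter_peaks(raw, group, min_rfu=min_rfu, bp_tolerance=bp_tolerance,
                            spacing_bp=spacing_bp)
        qc_log.append(
            f"{sample_id}\t{group_id}\tpeaks={len(raw)}\taccepted={len(kept)}"
        )
        props = standardise(assign_bins(kept, group, spacing_bp=spacing_bp))
        if props is None:
            qc_log.append(f"{sample_id}\t{group_id}\tFAILED: no peaks passed QC; dropped")
            continue
        specs.append(Spectratype(sample=metadata[sample_id], group_id=group_id, bins=props))
    if not specs:
        raise ValueError("no spectratype passed QC; nothing to assemble")
    matrix = build_matrix(specs)
    matrix.qc_log = qc_log
    return matrix
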
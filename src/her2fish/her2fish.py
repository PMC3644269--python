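"""Dual-probe HER2/CEP17 FISH scoring and inter-method concordance analysis.

This module implements, in pipeline order:

1. **Cell-level scoring** -- turn per-nucleus HER2 and CEP17 signal counts
   into tumour-level scores and categorical calls: the HER2/CEP17 ratio
   (ratio of means, with HER2 clusters capped at 16 signals), the ASCO/CAP
   three-way amplification call (<1.8 / 1.8-2.2 / >2.2) with the 60-cell ->
   100-cell equivocal reflex, two alternative amplification definitions
   (ratio >= 2.0; mean HER2 > 6.0), HER2 genetic heterogeneity (>5% and
   <50% of cells with per-cell ratio > 2.2), HER2-cluster positivity
   (>= 1% of cells), and chromosome-17 polysomy (mean CEP17 > 3.00).
2. **Concordance statistics** -- agreement between two scoring methods over
   a cohort: concordance rate, Cohen's kappa, Fisher/chi-square association
   tests, Pearson correlation, ordinary least squares, paired t tests, and
   reconstruction of a 2x2 joint table from published marginals plus a
   one-directional discordance constraint.
3. **Synthetic paired cohort** -- a generator of paired (method A / method B)
   cell tables for virtual tumours with amplified, equivocal, heterogeneous,
   polysomic and cluster-bearing subpopulations and a configurable
   multiplicative method bias, so the whole pipeline is testable end to end.
4. **Pipeline** -- score two cell tables, join on sample, and emit a full
   concordance report (TSV + JSON), optionally stratified by HER2 IHC score.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("her2fish")

__all__ = [
    "AmplificationCall",
    "BinaryCall",
    "CellObservation",
    "ScoringThresholds",
    "SampleScore",
    "CohortConfig",
    "JointTable",
    "AgreementResult",
    "ContinuousAgreement",
    "InputError",
    "UndefinedRatioError",
    "ReflexRequiredError",
    "ReconstructionError",
    "DegenerateTestError",
    "ConfigError",
    "effective_her2",
    "score_cells",
    "classify_asco",
    "classify_alt_ratio",
    "classify_mean_copies",
    "assess_heterogeneity",
    "assess_cluster_positive",
    "assess_polysomy",
    "score_with_reflex",
    "read_cell_table",
    "cells_from_frame",
    "score_table",
    "cohens_kappa",
    "concordance_rate",
    "reconstruct_binary_joint",
    "crosstab",
    "pearson_r",
    "linear_regression",
    "paired_t",
    "association_test",
    "categorical_agreement",
    "continuous_agreement",
    "generate_cohort",
    "paper_like_cohort",
    "run_comparison",
    "reproduce_published_tables",
    "PUBLISHED_TABLE1",
    "DISCORDANT_RATIOS_MANUAL",
    "DISCORDANT_RATIOS_AUTOMATED",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class InputError(ValueError):
    """Malformed input (negative counts, empty cell list, bad table)."""


class UndefinedRatioError(InputError):
    """Every scored cell has zero CEP17 signals; the ratio is undefined."""


class ReflexRequiredError(InputError):
    """Initial ratio is equivocal but no additional cells were supplied."""


class ReconstructionError(ValueError):
    """Joint table cannot be reconstructed from the given marginals."""

    def __init__(self, message: str, family_size: int | None = None):
        super().__init__(message)
        self.family_size = family_size


class DegenerateTestError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


class ConfigError(ValueError):
    """Invalid configuration values."""


# ---------------------------------------------------------------------------
# Thresholds and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringThresholds:
    """Cutoffs and protocol constants for HER2/CEP17 FISH scoring.

    Defaults follow the ASCO/CAP-era dual-probe conventions used in routine
    practice: equivocal band [1.8, 2.2] on the HER2/CEP17 ratio, the
    manufacturer's alternative >=2.0 cutoff, mean HER2 > 6.0 copies as an
    absolute-copy-number definition, heterogeneity strictly between 5% and
    50% of cells with per-cell ratio > 2.2, cluster positivity at >= 1% of
    cells, polysomy at mean CEP17 > 3.00, and the 60-cell initial read with
    reflex to 100 cells on an equivocal ratio.
    """

    ratio_low: float = 1.8
    ratio_high: float = 2.2
    ratio_alt: float = 2.0
    mean_copies_cutoff: float = 6.0
    het_lower_frac: float = 0.05
    het_upper_frac: float = 0.50
    cluster_pos_frac: float = 0.01
    cluster_cap: int = 16
    polysomy_cutoff: float = 3.00
    n_initial: int = 60
    n_reflex_total: int = 100
    min_areas: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.ratio_low < self.ratio_high):
            raise ConfigError("require 0 < ratio_low < ratio_high")
        if not (self.het_lower_frac < self.het_upper_frac):
            raise ConfigError("require het_lower_frac < het_upper_frac")
        if not (self.n_initial < self.n_reflex_total):
            raise ConfigError("require n_initial < n_reflex_total")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "ScoringThresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown threshold fields: {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringThresholds":
        """Load thresholds from a YAML or JSON config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_mapping(data)


DEFAULT_THRESHOLDS = ScoringThresholds()


# ---------------------------------------------------------------------------
# Cell-level scoring
# ---------------------------------------------------------------------------

class AmplificationCall(str, enum.Enum):
    """Three-way HER2 amplification status on the HER2/CEP17 ratio."""

    NON_AMPLIFIED = "non_amplified"
    EQUIVOCAL = "equivocal"
    AMPLIFIED = "amplified"


class BinaryCall(str, enum.Enum):
    """Two-way amplification status (alternative definitions)."""

    NON_AMPLIFIED = "non_amplified"
    AMPLIFIED = "amplified"


@dataclass(frozen=True)
class CellObservation:
    """One scored nucleus: HER2 and CEP17 signal counts plus a cluster flag.

    ``cluster`` marks a nucleus with >16 HER2 signals or coalesced signals
    that cannot be counted individually; such cells contribute exactly 16
    HER2 signals to the ratio.  ``area`` is an optional label for the tissue
    area the nucleus was scored in.
    """

    her2: int
    cep17: int
    cluster: bool = False
    area: str | None = None

    def __post_init__(self) -> None:
        if self.her2 < 0 or self.cep17 < 0:
            raise InputError(
                f"signal counts must be non-negative, got her2={self.her2} cep17={self.cep17}"
            )


def effective_her2(cell: CellObservation, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS) -> int:
    """HER2 count entering the ratio: the raw count, capped at ``cluster_cap``.

    Cluster cells count as exactly ``cluster_cap`` (16) signals.  An uncapped
    count above the cap without the cluster flag meets the cluster definition
    (>16 signals) and is capped too, with a warning.
    """
    if cell.cluster:
        return thresholds.cluster_cap
    if cell.her2 > thresholds.cluster_cap:
        warnings.warn(
            f"HER2 count {cell.her2} exceeds {thresholds.cluster_cap} without a cluster "
            "flag; treating as a cluster and capping",
            stacklevel=2,
        )
        return thresholds.cluster_cap
    return cell.her2


def _is_cluster(cell: CellObservation, thresholds: ScoringThresholds) -> bool:
    return cell.cluster or cell.her2 > thresholds.cluster_cap


def classify_asco(ratio: float, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS) -> AmplificationCall:
    """Three-way amplification call: <1.8 negative, [1.8, 2.2] equivocal, >2.2 amplified."""
    if not math.isfinite(ratio):
        raise InputError(f"ratio must be finite, got {ratio}")
    if ratio > thresholds.ratio_high:
        return AmplificationCall.AMPLIFIED
    if ratio >= thresholds.ratio_low:
        return AmplificationCall.EQUIVOCAL
    return AmplificationCall.NON_AMPLIFIED


def classify_alt_ratio(ratio: float, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS) -> BinaryCall:
    """Manufacturer's alternative cutoff: amplified iff ratio >= 2.0."""
    if not math.isfinite(ratio):
        raise InputError(f"ratio must be finite, got {ratio}")
    return BinaryCall.AMPLIFIED if ratio >= thresholds.ratio_alt else BinaryCall.NON_AMPLIFIED


def classify_mean_copies(mean_her2: float, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS) -> BinaryCall:
    """Absolute-copy-number definition: amplified iff mean HER2 > 6.0 signals/cell."""
    if not math.isfinite(mean_her2):
        raise InputError(f"mean_her2 must be finite, got {mean_her2}")
    return BinaryCall.AMPLIFIED if mean_her2 > thresholds.mean_copies_cutoff else BinaryCall.NON_AMPLIFIED


def assess_polysomy(mean_cep17: float, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Chromosome-17 polysomy: mean CEP17 strictly above 3.00 signals/cell."""
    if not math.isfinite(mean_cep17):
        raise InputError(f"mean_cep17 must be finite, got {mean_cep17}")
    return mean_cep17 > thresholds.polysomy_cutoff


def _frac_cells_ratio_gt_high(
    cells: Sequence[CellObservation], thresholds: ScoringThresholds
) -> float:
    """Fraction of evaluable cells whose per-cell effective ratio exceeds 2.2.

    Cells with zero CEP17 signals have no per-cell ratio and are excluded
    from the denominator (they stay in the mean computations).
    """
    evaluable = [c for c in cells if c.cep17 > 0]
    n_excluded = len(cells) - len(evaluable)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} cell(s) with CEP17=0 excluded from per-cell ratio tally",
            stacklevel=2,
        )
    if not evaluable:
        raise UndefinedRatioError("no cell has CEP17 > 0; per-cell ratios undefined")
    hits = sum(
        1
        for c in evaluable
        if effective_her2(c, thresholds) / c.cep17 > thresholds.ratio_high
    )
    return hits / len(evaluable)


def assess_heterogeneity(
    cells: Sequence[CellObservation], thresholds: ScoringThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """HER2 genetic heterogeneity: >5% and <50% of cells with per-cell ratio > 2.2.

    Both bounds are strict: exactly 5% or exactly 50% is not heterogeneous.
    """
    frac = _frac_cells_ratio_gt_high(cells, thresholds)
    return thresholds.het_lower_frac < frac < thresholds.het_upper_frac


def assess_cluster_positive(
    cells: Sequence[CellObservation], thresholds: ScoringThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """HER2-cluster-positive tumour: clusters in at least 1% of scored cells."""
    if not cells:
        raise InputError("empty cell list")
    n_clusters = sum(1 for c in cells if _is_cluster(c, thresholds))
    return n_clusters / len(cells) >= thresholds.cluster_pos_frac


@dataclass(frozen=True)
class SampleScore:
    """Per-tumour, per-method derived quantities and categorical calls."""

    n_cells: int
    mean_her2: float
    mean_cep17: float
    ratio: float
    frac_cells_ratio_gt_high: float
    asco_call: AmplificationCall
    alt_ratio_call: BinaryCall
    mean_copies_call: BinaryCall
    heterogeneity: bool
    cluster_positive: bool
    polysomy: bool
    reflex_performed: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["asco_call"] = self.asco_call.value
        d["alt_ratio_call"] = self.alt_ratio_call.value
        d["mean_copies_call"] = self.mean_copies_call.value
        return d


def score_cells(
    cells: Sequence[CellObservation],
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
    *,
    reflex_performed: bool = False,
) -> SampleScore:
    """Score one tumour/method from its raw cell observations.

    The tumour ratio is the ratio of means (total effective HER2 signals over
    total CEP17 signals), the standard dual-probe convention; HER2 counts are
    cluster-capped before averaging.  Area coverage below ``min_areas``
    distinct labels (when area labels are present) triggers a warning only.
    """
    if not cells:
        raise InputError("empty cell list")
    areas = {c.area for c in cells if c.area is not None}
    if areas and len(areas) < thresholds.min_areas:
        warnings.warn(
            f"only {len(areas)} distinct scored area(s); protocol asks for "
            f">= {thresholds.min_areas}",
            stacklevel=2,
        )
    eff = [effective_her2(c, thresholds) for c in cells]
    mean_her2 = sum(eff) / len(cells)
    mean_cep17 = sum(c.cep17 for c in cells) / len(cells)
    if mean_cep17 == 0:
        raise UndefinedRatioError("all cells have CEP17 = 0; tumour ratio undefined")
    ratio = mean_her2 / mean_cep17
    frac = _frac_cells_ratio_gt_high(cells, thresholds)
    return SampleScore(
        n_cells=len(cells),
        mean_her2=mean_her2,
        mean_cep17=mean_cep17,
        ratio=ratio,
        frac_cells_ratio_gt_high=frac,
        asco_call=classify_asco(ratio, thresholds),
        alt_ratio_call=classify_alt_ratio(ratio, thresholds),
        mean_copies_call=classify_mean_copies(mean_her2, thresholds),
        heterogeneity=thresholds.het_lower_frac < frac < thresholds.het_upper_frac,
        cluster_positive=assess_cluster_positive(cells, thresholds),
        polysomy=mean_cep17 > thresholds.polysomy_cutoff,
        reflex_performed=reflex_performed,
    )


def score_with_reflex(
    cells_initial: Sequence[CellObservation],
    cells_additional: Sequence[CellObservation] = (),
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
) -> SampleScore:
    """Score with the equivocal reflex rule.

    The initial read must contain exactly ``n_initial`` (60) cells.  If its
    ratio falls in the equivocal band [1.8, 2.2], the additional read of
    ``n_reflex_total - n_initial`` (40) cells is required and the final score
    is computed over the pooled 100 cells; otherwise the initial score is
    final and any additional cells are ignored.
    """
    if len(cells_initial) != thresholds.n_initial:
        raise InputError(
            f"initial read must have exactly {thresholds.n_initial} cells, got {len(cells_initial)}"
        )
    n_extra = thresholds.n_reflex_total - thresholds.n_initial
    if cells_additional and len(cells_additional) != n_extra:
        raise InputError(
            f"additional read must be empty or have exactly {n_extra} cells, "
            f"got {len(cells_additional)}"
        )
    initial = score_cells(cells_initial, thresholds)
    if thresholds.ratio_low <= initial.ratio <= thresholds.ratio_high:
        if not cells_additional:
            raise ReflexRequiredError(
                f"initial ratio {initial.ratio:.3f} is equivocal; "
                f"{n_extra} additional cells are required"
            )
        pooled = list(cells_initial) + list(cells_additional)
        return score_cells(pooled, thresholds, reflex_performed=True)
    return initial


# ---------------------------------------------------------------------------
# Cell-table I/O and per-sample scoring
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample_id", "her2", "cep17")


def read_cell_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited cell table (one row per scored nucleus).

    Dialect is chosen by extension (.csv -> comma, anything else -> tab)
    unless ``sep`` overrides it.  Required columns: sample_id, her2, cep17;
    optional: method, cell_id, cluster (0/1), area.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def cells_from_frame(df: pd.DataFrame) -> list[CellObservation]:
    """Convert cell-table rows to :class:`CellObservation` objects."""
    has_cluster = "cluster" in df.columns
    has_area = "area" in df.columns
    cells = []
    for row in df.itertuples(index=False):
        cells.append(
            CellObservation(
                her2=int(getattr(row, "her2")),
                cep17=int(getattr(row, "cep17")),
                cluster=bool(getattr(row, "cluster")) if has_cluster else False,
                area=str(getattr(row, "area")) if has_area else None,
            )
        )
    return cells


def score_table(
    df: pd.DataFrame, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Score every sample in a cell table; one output row per sample.

    Cells are ordered by ``cell_id`` when present (table order otherwise);
    the first ``n_initial`` form the initial read.  When a sample carries at
    least ``n_reflex_total`` cells the reflex rule applies; a sample with
    exactly ``n_initial`` cells and an equivocal initial ratio raises
    :class:`ReflexRequiredError`.  Samples with any other cell count are
    scored over all their cells, with a warning, and reflex is not applied.
    """
    rows = []
    for sample_id, group in df.groupby("sample_id", sort=True):
        if "cell_id" in group.columns:
            group = group.sort_values("cell_id", kind="stable")
        cells = cells_from_frame(group)
        n = len(cells)
        try:
            if n >= thresholds.n_reflex_total:
                extra = thresholds.n_reflex_total - thresholds.n_initial
                score = score_with_reflex(
                    cells[: thresholds.n_initial],
                    cells[thresholds.n_initial : thresholds.n_initial + extra],
                    thresholds,
                )
            elif n == thresholds.n_initial:
                score = score_with_reflex(cells, (), thresholds)
            else:
                warnings.warn(
                    f"sample {sample_id}: {n} cells (expected {thresholds.n_initial} or "
                    f">= {thresholds.n_reflex_total}); scoring all cells without reflex",
                    stacklevel=2,
                )
                score = score_cells(cells, thresholds)
        except InputError as exc:
            raise type(exc)(f"sample {sample_id}: {exc}") from exc
        rows.append({"sample_id": sample_id, **score.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concordance statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointTable:
    """K x K cross-classification of two methods' categorical calls.

    Rows are method A, columns method B, in the order of ``labels``.
    """

    labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        arr = np.asarray(self.counts)
        if arr.shape != (k, k):
            raise InputError(f"counts must be {k}x{k}, got {arr.shape}")
        if (arr < 0).any():
            raise InputError("counts must be non-negative")
        if arr.sum() == 0:
            raise InputError("empty table (N = 0)")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def n(self) -> int:
        return int(self.array.sum())

    @classmethod
    def from_array(cls, counts, labels: Sequence[str] | None = None) -> "JointTable":
        arr = np.asarray(counts, dtype=int)
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
        return cls(tuple(labels), tuple(tuple(int(x) for x in row) for row in arr))


def crosstab(
    calls_a: Sequence, calls_b: Sequence, labels: Sequence[str] | None = None
) -> JointTable:
    """Cross-classify paired categorical calls into a :class:`JointTable`.

    ``labels`` fixes category order (and keeps empty categories); by default
    categories are the sorted union of observed values.
    """
    a = [getattr(v, "value", v) for v in calls_a]
    b = [getattr(v, "value", v) for v in calls_b]
    if len(a) != len(b):
        raise InputError("call sequences must have equal length")
    if labels is None:
        labels = sorted(set(a) | set(b), key=str)
    labels = [getattr(v, "value", v) for v in labels]
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for va, vb in zip(a, b):
        counts[index[va], index[vb]] += 1
    return JointTable.from_array(counts, labels)


def concordance_rate(table: JointTable) -> float:
    """Fraction of samples assigned the same category by both methods."""
    arr = table.array
    return float(np.trace(arr) / arr.sum())


def cohens_kappa(table: JointTable) -> float:
    """Cohen's chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace / N) and p_e the agreement expected
    under independent raters with the observed marginals.  In the degenerate
    perfect case p_e = p_o = 1 (all mass in one diagonal cell) kappa is 1.0.
    """
    arr = table.array
    n = arr.sum()
    p_o = np.trace(arr) / n
    p_e = float(np.sum(arr.sum(axis=1) * arr.sum(axis=0)) / n**2)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def reconstruct_binary_joint(
    marginal_a: tuple[int, int],
    marginal_b: tuple[int, int],
    discordance: str = "unknown",
) -> JointTable:
    """Reconstruct the 2x2 joint table from two methods' (pos, neg) marginals.

    With ``discordance='a_pos_only'`` every disagreement is A-positive /
    B-negative (and symmetrically for ``'b_pos_only'``), which pins down the
    table uniquely.  With ``'unknown'`` the table is returned only if the
    marginals admit exactly one non-negative integer table; otherwise a
    :class:`ReconstructionError` carrying the family size is raised.
    """
    pos_a, neg_a = marginal_a
    pos_b, neg_b = marginal_b
    if min(pos_a, neg_a, pos_b, neg_b) < 0:
        raise ReconstructionError("marginals must be non-negative")
    n = pos_a + neg_a
    if pos_b + neg_b != n:
        raise ReconstructionError(
            f"inconsistent marginals: N_a={n} but N_b={pos_b + neg_b}"
        )
    labels = ("positive", "negative")
    if discordance == "a_pos_only":
        if pos_a < pos_b:
            raise ReconstructionError(
                f"a_pos_only requires pos_a >= pos_b, got {pos_a} < {pos_b}"
            )
        counts = [[pos_b, pos_a - pos_b], [0, neg_a]]
    elif discordance == "b_pos_only":
        if pos_b < pos_a:
            raise ReconstructionError(
                f"b_pos_only requires pos_b >= pos_a, got {pos_b} < {pos_a}"
            )
        counts = [[pos_a, 0], [pos_b - pos_a, neg_b]]
    elif discordance == "unknown":
        lo = max(0, pos_a + pos_b - n)
        hi = min(pos_a, pos_b)
        family = hi - lo + 1
        if family != 1:
            raise ReconstructionError(
                f"{family} tables are consistent with these marginals; "
                "a discordance direction is needed",
                family_size=family,
            )
        counts = [[lo, pos_a - lo], [pos_b - lo, neg_a - (pos_b - lo)]]
    else:
        raise InputError(f"unknown discordance mode {discordance!r}")
    return JointTable.from_array(counts, labels)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def linear_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, r_square)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("zero variance: regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student's t test on the differences x - y.

    Identical vectors give (0.0, 1.0); a constant non-zero difference has no
    variance to test against and raises :class:`DegenerateTestError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InputError("need equal-length vectors with at least 2 points")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    if np.ptp(d) == 0:
        raise DegenerateTestError("constant non-zero differences: t test degenerate")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def association_test(table: JointTable) -> tuple[float, str]:
    """Association p-value for a joint table; returns (p_value, test_name).

    2x2 tables use the two-sided Fisher exact test (point-probability
    convention: the p-value sums all tables as or less probable than the
    observed one).  Larger tables use the Pearson chi-square test; empty
    rows/columns are dropped jointly first, and a table that collapses below
    2x2 has no testable association (p = nan).
    """
    arr = table.array
    keep_rows = arr.sum(axis=1) > 0
    keep_cols = arr.sum(axis=0) > 0
    sub = arr[np.ix_(keep_rows, keep_cols)]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        return float("nan"), "none (single occupied category)"
    if sub.shape == (2, 2):
        res = stats.fisher_exact(sub, alternative="two-sided")
        return float(res.pvalue), "fisher_exact"
    res = stats.chi2_contingency(sub, correction=False)
    return float(res.pvalue), "chi2"


@dataclass(frozen=True)
class AgreementResult:
    """Categorical inter-method agreement for one parameter."""

    concordance_rate: float
    kappa: float
    p_value: float
    test: str
    n: int
    table: JointTable


@dataclass(frozen=True)
class ContinuousAgreement:
    """Continuous inter-method agreement (correlation, OLS, paired t)."""

    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    r_square: float
    t_stat: float
    t_p: float
    n: int


def categorical_agreement(
    calls_a: Sequence, calls_b: Sequence, labels: Sequence[str] | None = None
) -> AgreementResult:
    """Concordance rate, Cohen's kappa and association test for paired calls."""
    table = crosstab(calls_a, calls_b, labels)
    p, test = association_test(table)
    return AgreementResult(
        concordance_rate=concordance_rate(table),
        kappa=cohens_kappa(table),
        p_value=p,
        test=test,
        n=table.n,
        table=table,
    )


def continuous_agreement(x: Sequence[float], y: Sequence[float]) -> ContinuousAgreement:
    """Pearson correlation, OLS of y on x, and a paired t test of x vs y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept, r_square = linear_regression(x, y)  # raises on zero variance
    r_res = stats.pearsonr(x, y)
    t_stat, t_p = paired_t(x, y)
    return ContinuousAgreement(
        pearson_r=float(r_res.statistic),
        pearson_p=float(r_res.pvalue),
        slope=slope,
        intercept=intercept,
        r_square=r_square,
        t_stat=t_stat,
        t_p=t_p,
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Synthetic paired cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic paired FISH cohort.

    Each virtual tumour is assigned a latent state (amplified, equivocal,
    heterogeneous or non-amplified) and, independently, polysomy.  Per-cell
    signal counts are gamma-mixed Poisson draws around method-scaled means;
    method B's means are the shared tumour means multiplied by
    ``method_b_her2_factor`` and ``method_b_cep17_factor``, reproducing a
    systematic bias (defaults: method B sees ~8% fewer HER2 and ~11% more
    CEP17 signals).  ``cell_dispersion`` is the gamma shape of the per-cell
    intensity mixture: large values approach the Poisson limit and any value
    <= 0 selects the degenerate deterministic limit in which every count
    equals its rounded mean.  ``tumour_sigma`` is the log-scale SD of a
    per-tumour HER2 intensity shared between methods.  Each tumour emits
    ``cells_per_tumour`` initial-read cells plus a 40-cell reflex reserve.
    """

    n_tumours: int = 100
    frac_amplified: float = 0.44
    frac_equivocal: float = 0.06
    frac_heterogeneous: float = 0.17
    frac_polysomy: float = 0.04
    cluster_prob_given_amplified: float = 0.05
    her2_mean_nonamp: float = 2.0
    her2_mean_amp: float = 10.0
    cep17_mean: float = 2.0
    cep17_mean_polysomy: float = 3.5
    method_b_her2_factor: float = 0.92
    method_b_cep17_factor: float = 1.11
    cell_dispersion: float = 8.0
    tumour_sigma: float = 0.25
    cells_per_tumour: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_amplified,
            self.frac_equivocal,
            self.frac_heterogeneous,
            self.frac_polysomy,
            self.cluster_prob_given_amplified,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("all fractions must lie in [0, 1]")
        if self.frac_amplified + self.frac_equivocal + self.frac_heterogeneous > 1:
            raise ConfigError("state fractions must sum to at most 1")
        means = (
            self.her2_mean_nonamp,
            self.her2_mean_amp,
            self.cep17_mean,
            self.cep17_mean_polysomy,
        )
        if any(m <= 0 for m in means):
            raise ConfigError("all signal means must be positive")
        if self.n_tumours < 1 or self.cells_per_tumour < 1:
            raise ConfigError("n_tumours and cells_per_tumour must be positive")


_REFLEX_RESERVE = 40  # extra cells emitted per tumour so the reflex read exists


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Per-cell counts around ``means``: gamma-mixed Poisson, or rounded means
    in the deterministic limit (dispersion <= 0)."""
    if dispersion <= 0:
        return np.rint(means).astype(int)
    lam = rng.gamma(shape=dispersion, scale=means / dispersion)
    return rng.poisson(lam)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a paired synthetic cohort.

    Returns ``(truth, cells_a, cells_b)``: a per-tumour ground-truth table
    (sample_id, state, amplified_cell_fraction, polysomy, cluster_bearing,
    true_ratio) and two cell tables in the scoring input dialect, one per
    method.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tumours
    n_amp = round(config.frac_amplified * n)
    n_eq = round(config.frac_equivocal * n)
    n_het = round(config.frac_heterogeneous * n)
    if n_amp + n_eq + n_het > n:
        raise ConfigError("rounded state counts exceed the cohort size")
    states = (
        ["amplified"] * n_amp
        + ["equivocal"] * n_eq
        + ["heterogeneous"] * n_het
        + ["non_amplified"] * (n - n_amp - n_eq - n_het)
    )
    rng.shuffle(states)
    polysomy_flags = np.zeros(n, dtype=bool)
    polysomy_flags[rng.choice(n, size=round(config.frac_polysomy * n), replace=False)] = True

    n_cells = config.cells_per_tumour + _REFLEX_RESERVE
    factors = {"A": (1.0, 1.0), "B": (config.method_b_her2_factor, config.method_b_cep17_factor)}
    truth_rows = []
    cell_rows: dict[str, list] = {"A": [], "B": []}

    for i, state in enumerate(states):
        sample_id = f"T{i + 1:03d}"
        cep_mu = config.cep17_mean_polysomy if polysomy_flags[i] else config.cep17_mean
        latent = (
            float(rng.lognormal(-config.tumour_sigma**2 / 2, config.tumour_sigma))
            if config.tumour_sigma > 0
            else 1.0
        )
        # Per-cell HER2 means and the amplified-cell mask, shared between methods
        # (same underlying tumour composition; counts are drawn independently).
        if state == "amplified":
            amp_frac = 1.0
            her2_mu = np.full(n_cells, config.her2_mean_amp * latent)
            amp_mask = np.ones(n_cells, dtype=bool)
        elif state == "non_amplified":
            amp_frac = 0.0
            her2_mu = np.full(n_cells, config.her2_mean_nonamp * latent)
            amp_mask = np.zeros(n_cells, dtype=bool)
        elif state == "equivocal":
            # target ratio drawn inside the equivocal band; latent intensity is
            # not applied or the tumour would leave the band it defines
            amp_frac = 0.0
            target = rng.uniform(1.8, 2.2)
            her2_mu = np.full(n_cells, target * cep_mu)
            amp_mask = np.zeros(n_cells, dtype=bool)
        else:  # heterogeneous: 5-50% amplified cells (drawn with margin)
            amp_frac = float(rng.uniform(0.08, 0.45))
            k_amp = round(amp_frac * n_cells)
            amp_mask = np.zeros(n_cells, dtype=bool)
            amp_mask[rng.permutation(n_cells)[:k_amp]] = True
            her2_mu = np.where(
                amp_mask,
                config.her2_mean_amp * latent,
                config.her2_mean_nonamp * latent,
            )
        true_ratio = float(her2_mu.mean() / cep_mu)
        cluster_bearing = False
        for method, (f_her2, f_cep) in factors.items():
            her2 = _draw_counts(rng, her2_mu * f_her2, config.cell_dispersion)
            cep17 = _draw_counts(
                rng, np.full(n_cells, cep_mu * f_cep), config.cell_dispersion
            )
            cluster = np.zeros(n_cells, dtype=bool)
            if config.cluster_prob_given_amplified > 0 and amp_mask.any():
                hit = amp_mask & (
                    rng.random(n_cells) < config.cluster_prob_given_amplified
                )
                if hit.any():
                    cluster_bearing = True
                    # clusters carry an uncapped count >16; capping is the
                    # scorer's job, so the cap logic is exercised downstream
                    her2[hit] = 17 + rng.poisson(8, size=int(hit.sum()))
                    cluster[hit] = True
            for j in range(n_cells):
                cell_rows[method].append(
                    (sample_id, method, j + 1, int(her2[j]), int(cep17[j]), int(cluster[j]))
                )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "state": state,
                "amplified_cell_fraction": amp_frac,
                "polysomy": bool(polysomy_flags[i]),
                "cluster_bearing": cluster_bearing,
                "true_ratio": true_ratio,
            }
        )

    columns = ["sample_id", "method", "cell_id", "her2", "cep17", "cluster"]
    truth = pd.DataFrame(truth_rows)
    cells_a = pd.DataFrame(cell_rows["A"], columns=columns)
    cells_b = pd.DataFrame(cell_rows["B"], columns=columns)
    return truth, cells_a, cells_b


def paper_like_cohort(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A 100-tumour preset resembling a routine diagnostic cohort.

    Composition and method-bias factors follow the defaults of
    :class:`CohortConfig`; scored under method A the amplified fraction
    (ratio > 2.2) lands in a loose [0.40, 0.60] band and the cohort mean
    HER2 count in [5.0, 8.0].  This is a calibration band, not an exact
    reproduction of any real cohort.
    """
    return generate_cohort(CohortConfig(n_tumours=100, seed=seed))


# ---------------------------------------------------------------------------
# Pipeline: end-to-end comparison and reporting
# ---------------------------------------------------------------------------

CATEGORICAL_PARAMS: dict[str, tuple[str, ...]] = {
    "asco_binary": ("amplified", "not_amplified"),
    "asco_3class": ("non_amplified", "equivocal", "amplified"),
    "alt_ratio_call": ("amplified", "non_amplified"),
    "mean_copies_call": ("amplified", "non_amplified"),
    "heterogeneity": ("present", "absent"),
    "cluster_positive": ("present", "absent"),
    "polysomy": ("present", "absent"),
}

CONTINUOUS_PARAMS = ("mean_her2", "mean_cep17", "ratio", "frac_cells_ratio_gt_high")


def _categorical_series(scores: pd.DataFrame, param: str) -> pd.Series:
    if param == "asco_binary":
        return scores["asco_call"].map(
            lambda v: "amplified" if v == "amplified" else "not_amplified"
        )
    if param == "asco_3class":
        return scores["asco_call"]
    if param in ("heterogeneity", "cluster_positive", "polysomy"):
        return scores[param].map(lambda v: "present" if v else "absent")
    return scores[param]


def run_comparison(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
    ihc: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    allow_partial: bool = False,
) -> dict:
    """Score two methods' cell tables and compute the full concordance report.

    Samples are inner-joined on ``sample_id``; by default any sample present
    in only one table is an error (``allow_partial=True`` downgrades this to
    a warning).  ``ihc`` may give an immunohistochemistry score per sample
    (columns sample_id, ihc) used for stratified concordance rates.  When
    ``out_dir`` is given, per-sample score tables (TSV), the report (TSV and
    JSON) and a run log are written there; regeneration from identical
    inputs is byte-identical.
    """
    scores_a = score_table(cells_a, thresholds)
    scores_b = score_table(cells_b, thresholds)
    ids_a, ids_b = set(scores_a["sample_id"]), set(scores_b["sample_id"])
    shared = sorted(ids_a & ids_b)
    if not shared:
        raise InputError("no shared sample_id between the two methods")
    unmatched = sorted((ids_a | ids_b) - set(shared))
    if unmatched:
        msg = f"{len(unmatched)} sample(s) present in only one method: {unmatched[:5]}..."
        if not allow_partial:
            raise InputError(msg + " (pass allow_partial=True to proceed)")
        warnings.warn(msg, stacklevel=2)
    a = scores_a.set_index("sample_id").loc[shared]
    b = scores_b.set_index("sample_id").loc[shared]

    report: dict = {"n_samples": len(shared), "categorical": {}, "continuous": {}}
    for param, labels in CATEGORICAL_PARAMS.items():
        res = categorical_agreement(
            _categorical_series(a, param), _categorical_series(b, param), labels
        )
        report["categorical"][param] = {
            "concordance_rate": res.concordance_rate,
            "kappa": res.kappa,
            "p_value": res.p_value,
            "test": res.test,
            "n": res.n,
            "labels": list(res.table.labels),
            "table": [list(row) for row in res.table.counts],
        }
    nan = float("nan")
    for param in CONTINUOUS_PARAMS:
        x, y = a[param].to_numpy(), b[param].to_numpy()
        try:
            res = continuous_agreement(x, y)
            entry = {
                "pearson_r": res.pearson_r,
                "pearson_p": res.pearson_p,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_square": res.r_square,
                "t_stat": res.t_stat,
                "t_p": res.t_p,
                "n": res.n,
            }
        except DegenerateTestError:
            # constant parameter across the cohort: correlation/regression
            # undefined; the paired t is still meaningful when differences vary
            warnings.warn(f"{param}: zero variance; correlation undefined", stacklevel=2)
            try:
                t_stat, t_p = paired_t(x, y)
            except DegenerateTestError:
                t_stat = t_p = nan
            entry = {
                "pearson_r": nan,
                "pearson_p": nan,
                "slope": nan,
                "intercept": nan,
                "r_square": nan,
                "t_stat": t_stat,
                "t_p": t_p,
                "n": len(x),
            }
        report["continuous"][param] = entry
    if ihc is not None:
        report["strata"] = _stratified_concordance(a, b, ihc, shared)
    if out_dir is not None:
        _write_report(report, scores_a, scores_b, thresholds, Path(out_dir))
    return report


def _stratified_concordance(
    a: pd.DataFrame, b: pd.DataFrame, ihc: pd.DataFrame, shared: list
) -> dict:
    """Per-IHC-stratum concordance of the binary amplification call.

    Kappa is reported only in strata where both methods' calls occupy at
    least two categories; otherwise the concordance rate stands alone (kappa
    is undefined when a stratum is single-category).
    """
    if not {"sample_id", "ihc"} <= set(ihc.columns):
        raise InputError("ihc table requires columns sample_id, ihc")
    labels = ihc.set_index("sample_id")["ihc"]
    strata: dict = {}
    for stratum, ids in labels.groupby(labels):
        ids = [s for s in ids.index if s in a.index]
        if not ids:
            continue
        calls_a = _categorical_series(a.loc[ids], "asco_binary")
        calls_b = _categorical_series(b.loc[ids], "asco_binary")
        table = crosstab(calls_a, calls_b, CATEGORICAL_PARAMS["asco_binary"])
        entry = {"n": len(ids), "concordance_rate": concordance_rate(table)}
        occupied = sum(
            1 for i in range(len(table.labels)) if table.array[i].sum() + table.array[:, i].sum() > 0
        )
        if occupied >= 2:
            entry["kappa"] = cohens_kappa(table)
        strata[str(stratum)] = entry
    return strata


def _fmt(value: float) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _write_report(
    report: dict,
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    thresholds: ScoringThresholds,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    scores_a.to_csv(out_dir / "scores_A.tsv", sep="\t", index=False, float_format="%.6g")
    scores_b.to_csv(out_dir / "scores_B.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    lines = ["block\tparameter\tstatistic\tvalue"]
    for param, res in report["categorical"].items():
        lines.append(f"categorical\t{param}\tconcordance_pct\t{100 * res['concordance_rate']:.1f}")
        lines.append(f"categorical\t{param}\tkappa\t{_fmt(res['kappa'])}")
        p = res["p_value"]
        p_str = "<0.001" if (isinstance(p, float) and math.isfinite(p) and p < 0.001) else _fmt(p)
        lines.append(f"categorical\t{param}\tp_value ({res['test']})\t{p_str}")
    for param, res in report["continuous"].items():
        for stat in ("pearson_r", "slope", "intercept", "r_square", "t_stat", "t_p"):
            lines.append(f"continuous\t{param}\t{stat}\t{_fmt(res[stat])}")
    for stratum, entry in report.get("strata", {}).items():
        lines.append(
            f"strata\tihc={stratum}\tconcordance_pct\t{100 * entry['concordance_rate']:.1f}"
        )
        if "kappa" in entry:
            lines.append(f"strata\tihc={stratum}\tkappa\t{_fmt(entry['kappa'])}")
    (out_dir / "report.tsv").write_text("\n".join(lines) + "\n")
    log_lines = [
        f"n_samples={report['n_samples']}",
        "thresholds=" + json.dumps(dataclasses.asdict(thresholds), sort_keys=True),
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("report written to %s", out_dir)


# ---------------------------------------------------------------------------
# Published-table reproduction (built-in reference marginals)
# ---------------------------------------------------------------------------

#: Published concordance study of manual vs automated HER2 FISH on 100 core
#: biopsies: per-criterion (manual_positive, automated_positive) marginals,
#: with all discordance manual-positive/automated-negative, and the published
#: concordance (%) and kappa for comparison.
PUBLISHED_TABLE1: dict[str, dict] = {
    "ratio_gt_2.2": {
        "manual_positive": 50,
        "automated_positive": 46,
        "n": 100,
        "published_concordance_pct": 96.0,
        "published_kappa": 0.920,
    },
    "ratio_ge_2.0": {
        "manual_positive": 53,
        "automated_positive": 49,
        "n": 100,
        "published_concordance_pct": 96.0,
        "published_kappa": 0.920,
    },
    "mean_her2_gt_6.0": {
        "manual_positive": 45,
        "automated_positive": 42,
        "n": 100,
        "published_concordance_pct": 97.0,
        "published_kappa": 0.939,
    },
}

#: HER2/CEP17 ratios of the four tumours called amplified by manual FISH but
#: not by automated FISH in the published study.
DISCORDANT_RATIOS_MANUAL: tuple[float, ...] = (2.62, 2.74, 2.5, 3.14)
DISCORDANT_RATIOS_AUTOMATED: tuple[float, ...] = (2.05, 2.08, 1.49, 2.04)


def reproduce_published_tables() -> dict:
    """Rebuild each published 2x2 joint table from its marginals and recompute
    the agreement statistics alongside the published values."""
    out: dict = {}
    for name, entry in PUBLISHED_TABLE1.items():
        n = entry["n"]
        table = reconstruct_binary_joint(
            (entry["manual_positive"], n - entry["manual_positive"]),
            (entry["automated_positive"], n - entry["automated_positive"]),
            discordance="a_pos_only",
        )
        p, test = association_test(table)
        out[name] = {
            "table": [list(row) for row in table.counts],
            "concordance_pct": 100 * concordance_rate(table),
            "kappa": cohens_kappa(table),
            "p_value": p,
            "test": test,
            "published_concordance_pct": entry["published_concordance_pct"],
            "published_kappa": entry["published_kappa"],
        }
    out["discordant_cases"] = {
        "manual_calls": [classify_asco(r).value for r in DISCORDANT_RATIOS_MANUAL],
        "automated_calls": [classify_asco(r).value for r in DISCORDANT_RATIOS_AUTOMATED],
    }
    return out
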
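"""Before/after comparison statistics and the channel->measurement map.

Quantifies how ion-channel blockade changes the 21 intrinsic
measurements across a population of cells: per-cell percentage changes,
three heterogeneity metrics (SD, IQR, CV) of those changes, paired and
unpaired hypothesis tests (Wilcoxon signed-rank / rank-sum, Student's t,
Kruskal-Wallis), and the mapping matrix whose rows are channels and
columns measurements, with entries +/-/0 by significance and sign of the
median percentage change.  The two degeneracy signatures read off this
machinery are (1) a many-to-many but not all-to-all mapping matrix and
(2) large cell-to-cell variability in the magnitude of blockade effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError
from .records import MEASUREMENT_NAMES, MeasurementRecord

__all__ = [
    "percent_change",
    "percent_change_vector",
    "Heterogeneity",
    "heterogeneity",
    "compare_conditions",
    "kruskal_wallis",
    "ComparisonTable",
    "compare_table",
    "MappingMatrix",
    "mapping_matrix",
    "run_blockade_study",
    "records_to_frame",
]


def percent_change(before: float, after: float) -> float:
    """Percentage change ``100*(after - before)/before``, sign preserved.

    Applied to raw signed values: for a negative baseline such as RMP, a
    hyperpolarization (more negative) therefore yields a *positive*
    percentage.  A zero baseline makes the change undefined and returns
    NaN (the "undef" flag).
    """
    if before == 0 or not np.isfinite(before) or not np.isfinite(after):
        return float("nan")
    return 100.0 * (after - before) / before


def percent_change_vector(before: Sequence[float], after: Sequence[float]) -> np.ndarray:
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if b.shape != a.shape:
        raise ValueError(f"before {b.shape} and after {a.shape} differ in shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (a - b) / b
    pct[(b == 0) | ~np.isfinite(b) | ~np.isfinite(a)] = np.nan
    return pct


class Heterogeneity(NamedTuple):
    sd: float
    iqr: float
    cv: float


def heterogeneity(values: Sequence[float], mean_floor: float = 1e-12) -> Heterogeneity:
    """(SD, IQR, CV) of a vector of per-cell changes.

    SD uses the n-1 denominator; IQR is Q3 - Q1 with linear interpolation
    between order statistics; CV = SD/mean, NaN-flagged when the mean is
    indistinguishable from zero.
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"heterogeneity needs >= 2 finite values, got {x.size}")
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25.0, 75.0])  # linear interpolation
    mean = float(np.mean(x))
    cv = sd / mean if abs(mean) > mean_floor else float("nan")
    return Heterogeneity(sd=sd, iqr=float(q3 - q1), cv=cv)


def compare_conditions(
    before: Sequence[float],
    after: Sequence[float],
    design: str = "paired",
    family: str = "rank",
) -> tuple[float, float]:
    """Two-sample comparison; returns (statistic, two-sided p).

    design "paired"/"unpaired" x family "rank"/"t" dispatches to Wilcoxon
    signed-rank, Wilcoxon rank-sum (Mann-Whitney), paired t, or unpaired
    t.  The signed-rank test drops zero differences and uses the exact
    null for n <= 25 without ties, falling back to the tie-corrected
    normal approximation otherwise.
    """
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if design not in ("paired", "unpaired"):
        raise ValueError(f"unknown design {design!r}")
    if family not in ("rank", "t"):
        raise ValueError(f"unknown family {family!r}")
    if design == "paired" and b.size != a.size:
        raise ValueError(f"paired design needs equal lengths, got {b.size} and {a.size}")
    if min(b.size, a.size) < 2:
        raise ValueError("need n >= 2 per arm")

    if design == "paired":
        d = a - b
        if family == "rank":
            d_nz = d[d != 0]
            if d_nz.size == 0:
                raise DegenerateTestError(
                    "all paired differences are zero: signed-rank test undefined"
                )
            method = "approx" if d_nz.size > 25 else "exact"
            res = sps.wilcoxon(d_nz, alternative="two-sided", method=method)
            return float(res.statistic), float(res.pvalue)
        if np.all(d == 0):
            return 0.0, 1.0
        res = sps.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if family == "rank":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    res = sps.ttest_ind(a, b)
    stat = float(res.statistic)
    pval = float(res.pvalue)
    if np.isnan(stat) and np.array_equal(a, b):
        return 0.0, 1.0
    return stat, pval


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis H across k groups; returns (statistic, p)."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _summary(x: np.ndarray) -> dict[str, float]:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {k: float("nan") for k in ("mean", "sem", "median", "q1", "q3")}
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return {
        "mean": float(np.mean(x)),
        "sem": sem,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


@dataclass
class ComparisonTable:
    """Per-measurement before/after comparison across a cell population."""

    measurement: str
    before: np.ndarray
    after: np.ndarray
    pct_change: np.ndarray
    before_summary: Mapping[str, float]
    after_summary: Mapping[str, float]
    pct_summary: Mapping[str, float]
    het: Heterogeneity
    test: str
    statistic: float
    p_value: float

    def as_row(self) -> dict[str, float | str]:
        """Flat row in the standard reporting layout (before/after mean±SEM, %change, variability, test)."""
        return {
            "measurement": self.measurement,
            "n": int(np.sum(np.isfinite(self.pct_change))),
            "before_mean": self.before_summary["mean"],
            "before_sem": self.before_summary["sem"],
            "after_mean": self.after_summary["mean"],
            "after_sem": self.after_summary["sem"],
            "pct_mean": self.pct_summary["mean"],
            "pct_sem": self.pct_summary["sem"],
            "pct_median": self.pct_summary["median"],
            "sd": self.het.sd,
            "iqr": self.het.iqr,
            "cv": self.het.cv,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def compare_table(
    measurement: str,
    before: Sequence[float],
    after: Sequence[float],
    design: str = "paired",
    family: str = "rank",
) -> ComparisonTable:
    """Build the full before/after comparison for one measurement."""
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if design == "paired":
        keep = np.isfinite(b) & np.isfinite(a)
        b_t, a_t = b[keep], a[keep]
    else:
        b_t, a_t = b[np.isfinite(b)], a[np.isfinite(a)]
    pct = percent_change_vector(b, a) if b.shape == a.shape else np.full(b.shape, np.nan)
    test_name = {
        ("paired", "rank"): "wilcoxon_signed_rank",
        ("unpaired", "rank"): "wilcoxon_rank_sum",
        ("paired", "t"): "paired_t",
        ("unpaired", "t"): "unpaired_t",
    }[(design, family)]
    try:
        stat, p = compare_conditions(b_t, a_t, design=design, family=family)
    except DegenerateTestError:
        stat, p = float("nan"), 1.0
        test_name += "_degenerate"
    finite_pct = pct[np.isfinite(pct)]
    het = (
        heterogeneity(finite_pct)
        if finite_pct.size >= 2
        else Heterogeneity(float("nan"), float("nan"), float("nan"))
    )
    return ComparisonTable(
        measurement=measurement,
        before=b,
        after=a,
        pct_change=pct,
        before_summary=_summary(b),
        after_summary=_summary(a),
        pct_summary=_summary(pct),
        het=het,
        test=test_name,
        statistic=stat,
        p_value=p,
    )


@dataclass
class MappingMatrix:
    """Channels x measurements matrix of blockade effects.

    `signs` holds {+1, -1, 0}; an entry is nonzero iff the paired test
    rejected at `alpha` *and* the median percentage change cleared
    `effect_floor`.  `effects` (median % change), `p_values` and `n_used`
    carry each entry's provenance.
    """

    signs: pd.DataFrame
    effects: pd.DataFrame
    p_values: pd.DataFrame
    n_used: pd.DataFrame
    alpha: float
    effect_floor: float
    test: str = "wilcoxon_signed_rank"
    flags: Mapping[tuple[str, str], str] = field(default_factory=dict)

    @property
    def channels(self) -> list[str]:
        return list(self.signs.index)

    @property
    def measurements(self) -> list[str]:
        return list(self.signs.columns)

    def to_frame(self) -> pd.DataFrame:
        """Human-readable +/-/0 symbols."""
        sym = {1: "+", -1: "-", 0: "0"}
        return self.signs.map(lambda s: sym[int(s)])

    def row_nonzero(self) -> pd.Series:
        return (self.signs != 0).sum(axis=1)

    def col_nonzero(self) -> pd.Series:
        return (self.signs != 0).sum(axis=0)

    def summary(self) -> str:
        """Textual account of the two degeneracy signatures."""
        lines = ["Channel -> measurement mapping (rows: channels, cols: measurements)", ""]
        lines.append(self.to_frame().to_string())
        lines.append("")
        lines.append("Signature 1 - many-to-many, not all-to-all:")
        n_cols = len(self.measurements)
        for ch, k in self.row_nonzero().items():
            lines.append(
                f"  {ch}: alters {k}/{n_cols} measurements"
                + (" (none: zero-effect control)" if k == 0 else "")
            )
        multi = self.col_nonzero()
        shared = multi[multi >= 2]
        lines.append(
            f"  measurements altered by >= 2 channels: "
            + (", ".join(shared.index) if len(shared) else "none")
        )
        lines.append("")
        lines.append("Signature 2 - heterogeneous impact (|median % change| at nonzero entries):")
        for ch in self.channels:
            hits = [
                f"{m}: {self.effects.loc[ch, m]:+.1f}%"
                for m in self.measurements
                if self.signs.loc[ch, m] != 0
            ]
            if hits:
                lines.append(f"  {ch}: " + ", ".join(hits))
        return "\n".join(lines)


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Stack MeasurementRecords into a cells x measurements DataFrame."""
    return pd.DataFrame([r.as_dict() for r in records], columns=list(MEASUREMENT_NAMES))


def mapping_matrix(
    study: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    alpha: float = 0.05,
    effect_floor: float = 1.0,
    min_n: int = 5,
    family: str = "rank",
) -> MappingMatrix:
    """Build the channel->measurement mapping matrix from a blockade study.

    `study` maps each channel to its (before, after) population tables
    (cells x 21 measurements, paired by row).  Per entry, a paired test
    on before/after sets significance and the median percentage change
    sets the sign; entries with fewer than `min_n` usable pairs are
    flagged and left 0 rather than dropped.
    """
    channels = list(study)
    for ch, (b_df, a_df) in study.items():
        if len(b_df) != len(a_df):
            raise ValueError(f"{ch}: before ({len(b_df)}) and after ({len(a_df)}) row counts differ")
        if len(b_df) < min_n:
            raise ValueError(f"{ch}: need >= {min_n} cells, got {len(b_df)}")
    measurements = list(next(iter(study.values()))[0].columns)
    shape = (len(channels), len(measurements))
    signs = np.zeros(shape, dtype=int)
    effects = np.full(shape, np.nan)
    p_values = np.full(shape, np.nan)
    n_used = np.zeros(shape, dtype=int)
    flags: dict[tuple[str, str], str] = {}
    for i, ch in enumerate(channels):
        b_df, a_df = study[ch]
        for j, m in enumerate(measurements):
            b = b_df[m].to_numpy(dtype=np.float64)
            a = a_df[m].to_numpy(dtype=np.float64)
            keep = np.isfinite(b) & np.isfinite(a)
            n = int(keep.sum())
            n_used[i, j] = n
            pct = percent_change_vector(b[keep], a[keep])
            med = float(np.nanmedian(pct)) if np.any(np.isfinite(pct)) else float("nan")
            effects[i, j] = med
            if n < min_n:
                flags[(ch, m)] = f"insufficient n ({n} < {min_n})"
                continue
            try:
                _, p = compare_conditions(b[keep], a[keep], design="paired", family=family)
            except DegenerateTestError:
                flags[(ch, m)] = "degenerate (all differences zero)"
                p = 1.0
            p_values[i, j] = p
            if p < alpha and np.isfinite(med) and abs(med) >= effect_floor:
                signs[i, j] = 1 if med > 0 else -1
    idx = pd.Index(channels, name="channel")
    cols = pd.Index(measurements, name="measurement")
    return MappingMatrix(
        signs=pd.DataFrame(signs, index=idx, columns=cols),
        effects=pd.DataFrame(effects, index=idx, columns=cols),
        p_values=pd.DataFrame(p_values, index=idx, columns=cols),
        n_used=pd.DataFrame(n_used, index=idx, columns=cols),
        alpha=alpha,
        effect_floor=effect_floor,
        flags=flags,
    )


def run_blockade_study(
    models: Sequence,
    blockades: Sequence[str] = ("HCN", "Kir", "NaP", "TPQ_target"),
    fraction_blocked: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Virtual-knockout study over a model population.

    Runs the full measurement battery on every cell at baseline, then
    after blocking each listed channel by `fraction_blocked`, and returns
    per-channel (before, after) tables paired by cell.  Baseline records
    are computed once and shared across channels.
    """
    from .sim import BlockadeSpec, apply_blockade, run_protocol_suite

    rng = np.random.default_rng(seed)

    def run(model, tag: str, k: int) -> MeasurementRecord:
        s = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
        return run_protocol_suite(
            model, noise_sd=noise_sd, seed=s, meta={"cell": k, "condition": tag}
        )

    before = [run(m, "baseline", k) for k, m in enumerate(models)]
    before_df = records_to_frame(before)
    study: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for ch in blockades:
        spec = BlockadeSpec(channel=ch, fraction_blocked=fraction_blocked)
        after = [run(apply_blockade(m, spec), ch, k) for k, m in enumerate(models)]
        study[ch] = (before_df.copy(), records_to_frame(after))
    return study
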
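"""Trueness/precision evaluation and multi-group comparisons.

Accuracy is split per ISO 5725-1 into *trueness* — how close the central
tendency of the deviations is to zero (the reference value) — and
*precision* — how tightly repeated scans agree, summarised by the sample
standard deviation.  Groups are the scanning strategies; parameters are the
five linear deviations (ΔL, VE, VE_x, VE_y, VE_z, µm) and the three angular
ones (α_overall, α_coronal, α_axial, degrees).

Comparisons are nonparametric (the deviations are typically non-normal):
Kruskal-Wallis across a family, pairwise Mann-Whitney U at a
Bonferroni-adjusted threshold (0.05/3 → 0.017) for trueness, and pairwise
Brown-Forsythe (Levene on absolute deviations from group medians) for
precision.  Group differences are rendered as a compact letter display:
groups sharing a letter are not significantly different.
"""

from __future__ import annotations

import itertools
import json
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

#: Parameter columns of a measurement table, in report order.
LINEAR_PARAMS = ("deltaL_um", "VE_um", "VE_x_um", "VE_y_um", "VE_z_um")
ANGULAR_PARAMS = ("alpha_overall_deg", "alpha_coronal_deg", "alpha_axial_deg")
ALL_PARAMS = LINEAR_PARAMS + ANGULAR_PARAMS


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class InsufficientVariationError(ValueError):
    """A statistic is undefined on a constant sample."""


@dataclass(frozen=True)
class StrategyGroup:
    """One strategy's values for one parameter."""

    strategy_id: str
    parameter: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TruenessSummary:
    """Descriptive summary of one group: mean, sample SD, median, range and
    the t-based 95% confidence interval of the mean."""

    n: int
    M: float
    SD: float
    MED: float
    MIN: float
    MAX: float
    CI95_lower: float
    CI95_upper: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "M", "SD", "MED", "MIN", "MAX",
                 "CI95_lower", "CI95_upper")}


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis test: name, groups involved, statistic, p value and —
    for pairwise tests — the adjusted significance threshold."""

    test: str
    groups: tuple
    statistic: float
    p_value: float
    threshold: float = 0.05
    significant: bool = False

    def __post_init__(self):
        # normalise numpy scalars so results serialise as plain JSON
        object.__setattr__(self, "statistic", float(self.statistic))
        object.__setattr__(self, "p_value", float(self.p_value))
        object.__setattr__(self, "threshold", float(self.threshold))
        object.__setattr__(self, "significant", bool(self.significant))
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {"test": self.test, "groups": list(self.groups),
                "statistic": self.statistic, "p_value": self.p_value,
                "threshold": self.threshold, "significant": self.significant}


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def ci95_from_moments(mean: float, sd: float, n: int) -> tuple[float, float]:
    """t-based 95% confidence interval of the mean from printed moments:
    M ± t(0.975, n−1) · SD/√n."""
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 for a CI, got {n}")
    half = float(sps.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return mean - half, mean + half


def summarize(values) -> TruenessSummary:
    """Descriptive statistics with a t-based 95% CI of the mean:
    CI = M ± t(0.975, n−1) · SD/√n, SD with the n−1 denominator."""
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 for SD/CI, got {n}")
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    lo, hi = ci95_from_moments(m, sd, n)
    return TruenessSummary(
        n=n, M=m, SD=sd, MED=float(np.median(v)),
        MIN=float(np.min(v)), MAX=float(np.max(v)),
        CI95_lower=lo, CI95_upper=hi)


def summarize_group(group: StrategyGroup) -> TruenessSummary:
    return summarize(group.values)


# ---------------------------------------------------------------------------
# Normality
# ---------------------------------------------------------------------------

def test_normality(values, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk plus Kolmogorov-Smirnov checks of normality.

    The KS check is reported both as the Lilliefors variant (parameters
    estimated from the sample — the usual software default) and as the
    plain one-sample KS against N(mean, sd).  The sample is flagged
    non-normal when Shapiro-Wilk p < alpha.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise InsufficientDataError(f"need n >= 3 for normality tests, got {v.size}")
    if np.ptp(v) == 0:
        raise InsufficientVariationError("constant sample; normality undefined")
    sw_stat, sw_p = sps.shapiro(v)
    lf_stat, lf_p = lilliefors(v, dist="norm")
    ks_stat, ks_p = sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return {
        "shapiro_wilk": ComparisonResult("shapiro_wilk", (), float(sw_stat),
                                         float(sw_p), alpha, sw_p < alpha),
        "ks_lilliefors": ComparisonResult("ks_lilliefors", (), float(lf_stat),
                                          float(lf_p), alpha, lf_p < alpha),
        "ks_plain": ComparisonResult("ks_plain", (), float(ks_stat),
                                     float(ks_p), alpha, ks_p < alpha),
        "non_normal": bool(sw_p < alpha),
    }


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list[StrategyGroup],
                   alpha: float = 0.05) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected) across >= 2 groups; p from the
    chi-square approximation with k−1 df.  If every observation is
    identical the test is vacuous: H = 0, p = 1 by convention."""
    if len(groups) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs >= 2 groups")
    for g in groups:
        if g.n < 2:
            raise InsufficientDataError(
                f"group {g.strategy_id!r} has n = {g.n} < 2")
    samples = [g.values for g in groups]
    ids = tuple(g.strategy_id for g in groups)
    if np.ptp(np.concatenate(samples)) == 0:
        return ComparisonResult("kruskal_wallis", ids, 0.0, 1.0, alpha, False)
    h, p = sps.kruskal(*samples)
    return ComparisonResult("kruskal_wallis", ids, float(h), float(p),
                            alpha, p < alpha)


def bonferroni_threshold(family_alpha: float, m: int) -> float:
    """Adjusted per-comparison threshold, reported to 3 decimals
    (0.05 / 3 → 0.017)."""
    if m < 1:
        raise ValueError("comparison count m must be >= 1")
    return round(family_alpha / m, 3)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact when min(n) <= 8 and there are no
    ties, otherwise the normal approximation with tie and continuity
    correction.  Returns (U, p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty group in Mann-Whitney test")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_mannwhitney(groups: list[StrategyGroup],
                         family_alpha: float = 0.05,
                         m: int | None = None) -> list[ComparisonResult]:
    """All pairwise Mann-Whitney U tests within one comparison family at
    the Bonferroni-adjusted threshold family_alpha / m (m defaults to the
    number of pairs)."""
    pairs = list(itertools.combinations(groups, 2))
    if not pairs:
        raise InsufficientDataError("need >= 2 groups for pairwise tests")
    thr = bonferroni_threshold(family_alpha, m if m is not None else len(pairs))
    out = []
    for ga, gb in pairs:
        u, p = mann_whitney(ga.values, gb.values)
        out.append(ComparisonResult(
            "mann_whitney_u", (ga.strategy_id, gb.strategy_id),
            u, p, thr, p < thr))
    return out


def brown_forsythe(a, b) -> tuple[float, float]:
    """Brown-Forsythe dispersion test between two samples: Levene's test on
    absolute deviations from the group medians.  Returns (W, p); if the
    absolute deviations carry no variation at all the test is vacuous
    (W = 0, p = 1)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("Brown-Forsythe needs n >= 3 per group")
    dev = np.concatenate([np.abs(a - np.median(a)), np.abs(b - np.median(b))])
    if np.ptp(dev) == 0:
        return 0.0, 1.0
    w, p = sps.levene(a, b, center="median")
    return float(w), float(p)


def compare_precision(groups: list[StrategyGroup],
                      family_alpha: float = 0.05,
                      m: int | None = None) -> list[ComparisonResult]:
    """Pairwise Brown-Forsythe comparisons of dispersion (the precision
    family), at the same Bonferroni-adjusted threshold as trueness."""
    pairs = list(itertools.combinations(groups, 2))
    if not pairs:
        raise InsufficientDataError("need >= 2 groups for pairwise tests")
    thr = bonferroni_threshold(family_alpha, m if m is not None else len(pairs))
    out = []
    for ga, gb in pairs:
        w, p = brown_forsythe(ga.values, gb.values)
        out.append(ComparisonResult(
            "brown_forsythe", (ga.strategy_id, gb.strategy_id),
            w, p, thr, p < thr))
    return out


# ---------------------------------------------------------------------------
# Compact letter display
# ---------------------------------------------------------------------------

def assign_letters(group_ids: list[str],
                   results: list[ComparisonResult],
                   uppercase: bool = True) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Two groups share at least one letter iff their pairwise comparison was
    not significant.  Pairs absent from ``results`` are treated as
    non-significant.  ``uppercase`` selects the letter case (uppercase for
    trueness, lowercase for precision).
    """
    sig = {frozenset(r.groups): r.significant for r in results}
    for key in sig:
        if not key <= set(group_ids):
            raise ValueError(f"comparison involves unknown groups: {key}")
    # Insert-and-absorb: start with one letter covering everyone, split on
    # each significant pair, drop letter sets contained in another.
    letters: list[set] = [set(group_ids)]
    for pair, significant in sorted(sig.items(),
                                    key=lambda kv: sorted(kv[0])):
        if not significant:
            continue
        a, b = sorted(pair)
        new_letters = []
        for ls in letters:
            if a in ls and b in ls:
                new_letters.extend([ls - {a}, ls - {b}])
            else:
                new_letters.append(ls)
        letters = [ls for ls in new_letters if ls]
        letters = [ls for i, ls in enumerate(letters)
                   if not any(ls < other or (ls == other and i > j)
                              for j, other in enumerate(letters))]
    alphabet = string.ascii_uppercase if uppercase else string.ascii_lowercase
    if len(letters) > len(alphabet):  # pragma: no cover - 9 groups max here
        alphabet = [a + b for a in alphabet for b in alphabet]
    out = {gid: "" for gid in group_ids}
    for letter, ls in zip(alphabet, letters):
        for gid in sorted(ls):
            out[gid] += letter
    return out


def check_letter_soundness(letters: dict[str, str],
                           results: list[ComparisonResult]) -> bool:
    """Sharing a letter must be equivalent to non-significance, for every
    tested pair."""
    for r in results:
        a, b = r.groups
        share = bool(set(letters[a]) & set(letters[b]))
        if share == r.significant:
            return False
    return True


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

_GRID_SEGMENTS = ("F", "H", "S")
_GRID_MOVEMENTS = ("L", "Z", "C")


def comparison_families(strategies: list[str]) -> list[list[str]]:
    """Comparison families for the Bonferroni correction.

    For the full 3x3 strategy grid (F/H/S segmentation x L/Z/C movement)
    the families are the six factor-level triples: the three movements
    within each segmentation, and the three segmentations within each
    movement (m = 3 pairs each, threshold 0.05/3 → 0.017).  Any other
    strategy set forms a single all-pairs family.
    """
    grid = {f"{s}{m}" for s in _GRID_SEGMENTS for m in _GRID_MOVEMENTS}
    if set(strategies) == grid:
        fams = [[f"{s}{m}" for m in _GRID_MOVEMENTS] for s in _GRID_SEGMENTS]
        fams += [[f"{s}{m}" for s in _GRID_SEGMENTS] for m in _GRID_MOVEMENTS]
        return fams
    return [sorted(strategies)]


@dataclass
class AccuracyReport:
    """Per-parameter descriptives, omnibus and pairwise comparisons, and
    compact letter displays (uppercase = trueness, lowercase = precision)."""

    strategies: list
    summaries: dict = field(default_factory=dict)   # param -> {sid: summary}
    normality: dict = field(default_factory=dict)   # param -> {sid: dict}
    kruskal: dict = field(default_factory=dict)     # param -> [per family]
    trueness_pairwise: dict = field(default_factory=dict)
    precision_pairwise: dict = field(default_factory=dict)
    trueness_letters: dict = field(default_factory=dict)
    precision_letters: dict = field(default_factory=dict)

    def _table(self, params) -> pd.DataFrame:
        rows = []
        for sid in self.strategies:
            row = {"strategy": sid}
            for p in params:
                s = self.summaries[p][sid]
                row[f"{p}_M"] = s.M
                row[f"{p}_SD"] = s.SD
                row[f"{p}_MED"] = s.MED
                row[f"{p}_MIN"] = s.MIN
                row[f"{p}_MAX"] = s.MAX
                row[f"{p}_CI95_lower"] = s.CI95_lower
                row[f"{p}_CI95_upper"] = s.CI95_upper
                row[f"{p}_letters"] = (self.trueness_letters[p][sid]
                                       + self.precision_letters[p][sid])
            rows.append(row)
        return pd.DataFrame(rows)

    def linear_table(self) -> pd.DataFrame:
        return self._table(LINEAR_PARAMS)

    def angular_table(self) -> pd.DataFrame:
        return self._table(ANGULAR_PARAMS)

    def to_dict(self) -> dict:
        def comps(d):
            return {p: [c.to_dict() for c in lst] for p, lst in d.items()}
        return {
            "strategies": list(self.strategies),
            "summaries": {p: {sid: s.to_dict() for sid, s in by.items()}
                          for p, by in self.summaries.items()},
            "normality": {p: {sid: {k: (v.to_dict()
                                        if isinstance(v, ComparisonResult)
                                        else v)
                                    for k, v in res.items()}
                              for sid, res in by.items()}
                          for p, by in self.normality.items()},
            "kruskal_wallis": comps(self.kruskal),
            "trueness_pairwise": comps(self.trueness_pairwise),
            "precision_pairwise": comps(self.precision_pairwise),
            "trueness_letters": self.trueness_letters,
            "precision_letters": self.precision_letters,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def build_report(records: pd.DataFrame, family_alpha: float = 0.05,
                 m: int | None = 3) -> AccuracyReport:
    """Assemble the full accuracy report from a measurement table.

    ``records`` needs a ``strategy`` column plus the eight parameter
    columns.  Trueness comparisons run on the signed deviations, precision
    comparisons on dispersion; both use Bonferroni threshold
    family_alpha / m within each comparison family.
    """
    missing = [c for c in ("strategy",) + ALL_PARAMS
               if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing columns: {missing}")
    strategies = list(dict.fromkeys(records["strategy"]))
    if len(strategies) < 2:
        raise InsufficientDataError(
            "group comparisons need >= 2 strategies in the records")
    families = comparison_families(strategies)
    report = AccuracyReport(strategies=strategies)
    grouped = {sid: records[records["strategy"] == sid] for sid in strategies}
    for param in ALL_PARAMS:
        groups = {sid: StrategyGroup(sid, param,
                                     grouped[sid][param].to_numpy())
                  for sid in strategies}
        report.summaries[param] = {sid: summarize_group(g)
                                   for sid, g in groups.items()}
        report.normality[param] = {sid: test_normality(g.values)
                                   for sid, g in groups.items()}
        kw, tp, pp = [], [], []
        for fam in families:
            fam_groups = [groups[sid] for sid in fam]
            fam_m = m if m is not None else math.comb(len(fam), 2)
            if len(fam) >= 2:
                kw.append(kruskal_wallis(fam_groups))
                tp.extend(pairwise_mannwhitney(fam_groups, family_alpha,
                                               m=fam_m))
                pp.extend(compare_precision(fam_groups, family_alpha,
                                            m=fam_m))
        report.kruskal[param] = kw
        report.trueness_pairwise[param] = tp
        report.precision_pairwise[param] = pp
        report.trueness_letters[param] = assign_letters(
            strategies, tp, uppercase=True)
        report.precision_letters[param] = assign_letters(
            strategies, pp, uppercase=False)
        for letters, results in ((report.trueness_letters[param], tp),
                                 (report.precision_letters[param], pp)):
            if not check_letter_soundness(letters, results):
                raise AssertionError(
                    f"letter display inconsistent for {param}")
    return report
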
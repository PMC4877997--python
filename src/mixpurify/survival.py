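"""Quantile-dichotomized survival association of soluble mediators.

Reproduces the ascites-mediator relapse-free-survival (RFS) workflow:
patients are split at an empirical quantile of a mediator's concentration
(best-fit over a small quantile grid), groups are compared by the
Mantel-Cox logrank test with the logrank (observed/expected) hazard ratio,
Kaplan-Meier median survival per group, trichotomized two-mediator synergy
groups, and a Benjamini-Hochberg gate over a family of mediator tests.
A seeded synthetic-cohort generator supports power and calibration studies.

The model-style entry point is :class:`MediatorSurvival`, built from a
cohort table (``patient_id``, ``rfs_months``, ``event`` plus one column per
mediator); ``fit(mediator)`` returns a :class:`KMResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: quantiles scanned by the best-fit search
DEFAULT_QUANTILE_GRID = (0.20, 0.25, 0.33, 0.50, 0.66, 0.75, 0.80)
#: minimum observation period (months) for cohort inclusion
MIN_FOLLOWUP_MONTHS = 12.0


# ---------------------------------------------------------------------------
# cohort handling

def filter_min_followup(
    cohort: pd.DataFrame,
    min_months: float = MIN_FOLLOWUP_MONTHS,
    drop_early_events: bool = False,
) -> pd.DataFrame:
    """Apply the minimum-observation-period inclusion rule.

    Patients censored before ``min_months`` are removed; patients who
    relapsed early are kept by default (their observation ended with an
    informative event) unless ``drop_early_events`` is set.
    """
    keep = (cohort["rfs_months"] >= min_months) | (
        cohort["event"].astype(bool) if not drop_early_events
        else pd.Series(False, index=cohort.index)
    )
    return cohort.loc[keep].copy()


def dichotomize(values: Sequence[float] | pd.Series, q: float) -> np.ndarray:
    """Split values into ``low``/``high`` at the empirical ``q``-quantile.

    The threshold uses linear (type-7) interpolation; ``high`` means
    strictly above the threshold.
    """
    arr = np.asarray(values, dtype=float)
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must lie strictly inside (0, 1)")
    threshold = np.quantile(arr, q)  # numpy default = type-7 linear
    labels = np.where(arr > threshold, "high", "low")
    if len(set(labels)) < 2:
        raise ValueError(
            f"degenerate split at quantile {q}: all patients on one side"
        )
    return labels


def trichotomize(
    values_a: Sequence[float],
    values_b: Sequence[float],
    qa: float,
    qb: float,
) -> np.ndarray:
    """Compose two dichotomizations into synergy groups
    ``both_high`` / ``one_high`` / ``both_low``."""
    la = dichotomize(values_a, qa) == "high"
    lb = dichotomize(values_b, qb) == "high"
    n_high = la.astype(int) + lb.astype(int)
    return np.array(["both_low", "one_high", "both_high"])[n_high]


# ---------------------------------------------------------------------------
# logrank machinery

@dataclass
class LogrankTable:
    """Observed/expected event counts of a two-group Mantel-Cox test."""

    observed: dict[str, float]
    expected: dict[str, float]
    variance: float
    chi2: float
    p: float
    hazard_ratio: float


def logrank(
    groups: Sequence[str] | np.ndarray,
    rfs: Sequence[float] | np.ndarray,
    events: Sequence[bool] | np.ndarray,
) -> LogrankTable:
    """Two-group Mantel-Cox logrank test with the logrank hazard ratio.

    At every distinct event time the observed events in each group are
    compared with their hypergeometric expectation given the risk sets;
    the test statistic is ``(O1 - E1)^2 / V`` on one degree of freedom and
    the hazard ratio is ``(O1/E1) / (O2/E2)`` with group 1 the
    lexicographically *later* label (``high`` before ``low`` means HR is
    high-versus-low, matching the usual reading).

    Identical group survival gives HR = 1 and p = 1 exactly.
    """
    g = np.asarray(groups)
    t = np.asarray(rfs, dtype=float)
    e = np.asarray(events, dtype=bool)
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError(f"logrank needs exactly 2 groups, got {labels}")
    if set(labels) == {"high", "low"}:
        labels = ["high", "low"]  # numerator group first
    g1 = g == labels[0]
    if e.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(t[e])
    o1 = e1 = v = 0.0
    o2 = e2 = 0.0
    for tau in event_times:
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (e & (t == tau)).sum()
        d1 = (e & (t == tau) & g1).sum()
        o1 += d1
        o2 += d - d1
        exp1 = d * n1 / n
        e1 += exp1
        e2 += d - exp1
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    # O/E hazard ratio; 0 or inf when one group has no events
    rate1 = o1 / e1 if e1 > 0 else math.nan
    rate2 = o2 / e2 if e2 > 0 else math.nan
    if rate2 == 0:
        hr = math.inf if rate1 > 0 else 1.0
    else:
        hr = rate1 / rate2
    return LogrankTable(
        observed={labels[0]: o1, labels[1]: o2},
        expected={labels[0]: e1, labels[1]: e2},
        variance=float(v),
        chi2=float(chi2),
        p=float(p),
        hazard_ratio=float(hr),
    )


def logrank_permutation_p(
    groups: Sequence[str] | np.ndarray,
    rfs: Sequence[float] | np.ndarray,
    events: Sequence[bool] | np.ndarray,
    mid_p: bool = False,
) -> tuple[float, int]:
    """Exact permutation p-value of the logrank statistic (small cohorts).

    Enumerates every assignment of the observed group sizes to patients and
    compares the permuted chi-square statistics with the observed one.
    With ``mid_p`` the ties contribute half, the usual correction for the
    discreteness of the permutation distribution.  Returns the p-value and
    the number of assignments enumerated; intended for n of about 10 or
    fewer (the enumeration is combinatorial).
    """
    from itertools import combinations

    g = np.asarray(groups)
    t = np.asarray(rfs, dtype=float)
    e = np.asarray(events, dtype=bool)
    obs = logrank(g, t, e).chi2
    labels = sorted(set(g.tolist()))
    k = int((g == labels[0]).sum())
    n = len(g)
    gt = eq = total = 0
    for idx in combinations(range(n), k):
        lab = np.full(n, labels[1], dtype=object)
        lab[list(idx)] = labels[0]
        try:
            c = logrank(lab, t, e).chi2
        except ValueError:
            continue
        total += 1
        if c > obs + 1e-12:
            gt += 1
        elif c >= obs - 1e-12:
            eq += 1
    if total == 0:
        raise ValueError("no admissible permutations")
    p = (gt + 0.5 * eq) / total if mid_p else (gt + eq) / total
    return float(p), total


def km_median(
    rfs: Sequence[float], events: Sequence[bool]
) -> float:
    """Kaplan-Meier median survival: the first time the survival curve
    drops to <= 0.5, or ``inf`` when never reached."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(rfs, dtype=float), np.asarray(events, dtype=bool))
    return float(kmf.median_survival_time_)


# ---------------------------------------------------------------------------
# results containers and the best-fit search

@dataclass
class KMResult:
    """One mediator's dichotomized survival comparison."""

    mediator: str
    quantile: float
    n_low: int
    n_high: int
    logrank_p: float
    hazard_ratio: float
    median_low: float
    median_high: float
    significant: bool | None = None
    multiple_cutpoint_caveat: bool = False

    @property
    def n(self) -> int:
        return self.n_low + self.n_high

    def summary(self) -> str:
        def fmt_med(m: float) -> str:
            return "not reached" if math.isinf(m) else f"{m:.1f} mo"

        lines = [
            f"Mediator {self.mediator}: Q = {self.quantile} "
            f"(n = {self.n}; {self.n_low} low / {self.n_high} high)",
            f"  logrank p = {self.p_formatted}    HR (high vs low) = "
            f"{self.hazard_ratio:.2f}",
            f"  median RFS: low {fmt_med(self.median_low)}, "
            f"high {fmt_med(self.median_high)}",
        ]
        if self.significant is not None:
            lines.append(f"  significant after BH gate: {self.significant}")
        if self.multiple_cutpoint_caveat:
            lines.append(
                "  note: quantile chosen by grid search; p is optimistic"
            )
        return "\n".join(lines)

    @property
    def p_formatted(self) -> str:
        return "<0.0001" if self.logrank_p < 1e-4 else f"{self.logrank_p:.4f}"


def analyze_dichotomized(
    values: Sequence[float],
    rfs: Sequence[float],
    events: Sequence[bool],
    q: float,
    mediator: str = "",
) -> KMResult:
    """Dichotomize at one quantile and run the logrank comparison."""
    values = np.asarray(values, dtype=float)
    rfs = np.asarray(rfs, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = dichotomize(values, q)
    table = logrank(labels, rfs, events)
    lo = labels == "low"
    return KMResult(
        mediator=mediator,
        quantile=q,
        n_low=int(lo.sum()),
        n_high=int((~lo).sum()),
        logrank_p=table.p,
        hazard_ratio=table.hazard_ratio,
        median_low=km_median(rfs[lo], events[lo]),
        median_high=km_median(rfs[~lo], events[~lo]),
    )


def best_fit_quantile(
    values: Sequence[float],
    rfs: Sequence[float],
    events: Sequence[bool],
    grid: Sequence[float] = DEFAULT_QUANTILE_GRID,
    mediator: str = "",
) -> tuple[float, KMResult]:
    """Scan a quantile grid and return the cutpoint minimizing logrank p.

    Ties prefer the smaller quantile; degenerate splits are skipped.  The
    returned result carries ``multiple_cutpoint_caveat`` whenever more than
    one cutpoint was tried, because the minimum p over a grid is optimistic.
    """
    if len(grid) == 0:
        raise ValueError("empty quantile grid")
    best: KMResult | None = None
    for q in sorted(grid):
        try:
            res = analyze_dichotomized(values, rfs, events, q, mediator)
        except ValueError:
            continue  # degenerate split at this quantile
        if best is None or res.logrank_p < best.logrank_p:
            best = res
    if best is None:
        raise ValueError("every quantile in the grid gave a degenerate split")
    best.multiple_cutpoint_caveat = len(grid) > 1
    return best.quantile, best


def analyze_trichotomized(
    values_a: Sequence[float],
    values_b: Sequence[float],
    rfs: Sequence[float],
    events: Sequence[bool],
    qa: float,
    qb: float,
) -> dict[str, object]:
    """Two-mediator synergy analysis with pairwise logrank comparisons.

    Returns group sizes, Kaplan-Meier median survival per group and the
    logrank tables for each pair of groups present.
    """
    groups = trichotomize(values_a, values_b, qa, qb)
    rfs = np.asarray(rfs, dtype=float)
    events = np.asarray(events, dtype=bool)
    out: dict[str, object] = {"groups": groups}
    sizes, medians = {}, {}
    present = [g for g in ("both_high", "one_high", "both_low")
               if (groups == g).any()]
    for gname in present:
        mask = groups == gname
        sizes[gname] = int(mask.sum())
        medians[gname] = km_median(rfs[mask], events[mask])
    out["sizes"] = sizes
    out["km_median"] = medians
    pairwise = {}
    for i, ga in enumerate(present):
        for gb in present[i + 1:]:
            mask = (groups == ga) | (groups == gb)
            sub = np.where(groups[mask] == ga, "high", "low")
            try:
                pairwise[(ga, gb)] = logrank(sub, rfs[mask], events[mask])
            except ValueError:
                pairwise[(ga, gb)] = None
    out["pairwise"] = pairwise
    return out


def bh_gate(
    pvalues: Sequence[float], fdr: float = 0.10, alpha: float = 0.05
) -> np.ndarray:
    """Significance flags: p < ``alpha`` AND p below its Benjamini-Hochberg
    step-up critical value at the given FDR."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject & (p < alpha)


def pearson_matrix(mediators: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of mediator levels."""
    return mediators.corr(method="pearson")


# ---------------------------------------------------------------------------
# model-style wrapper

class MediatorSurvival:
    """Survival-association model over a cohort's soluble mediators.

    Parameters
    ----------
    cohort : pandas.DataFrame
        Columns ``patient_id``, ``rfs_months``, ``event`` plus one numeric
        column per mediator; missing mediator values drop the patient from
        that mediator's analysis only.
    min_followup : float
        Minimum observation period (months); censored patients below it
        are excluded up front.
    """

    def __init__(
        self, cohort: pd.DataFrame, min_followup: float = MIN_FOLLOWUP_MONTHS
    ) -> None:
        required = {"patient_id", "rfs_months", "event"}
        if not required.issubset(cohort.columns):
            raise ValueError(f"cohort must have columns {sorted(required)}")
        if (cohort["rfs_months"] <= 0).any():
            raise ValueError("rfs_months must be positive")
        self.cohort = filter_min_followup(cohort, min_followup)
        self.mediators = [
            c for c in cohort.columns if c not in required
        ]

    def _mediator_frame(self, mediator: str) -> pd.DataFrame:
        sub = self.cohort[["rfs_months", "event", mediator]].dropna(
            subset=[mediator]
        )
        return sub

    def fit(
        self,
        mediator: str,
        quantile: float | None = None,
        grid: Sequence[float] = DEFAULT_QUANTILE_GRID,
    ) -> KMResult:
        """Dichotomized analysis of one mediator, at a fixed quantile or —
        when ``quantile`` is None — at the best-fit grid quantile."""
        sub = self._mediator_frame(mediator)
        if quantile is not None:
            return analyze_dichotomized(
                sub[mediator], sub["rfs_months"], sub["event"],
                quantile, mediator,
            )
        _, res = best_fit_quantile(
            sub[mediator], sub["rfs_months"], sub["event"], grid, mediator
        )
        return res

    def fit_all(
        self,
        quantiles: Mapping[str, float] | None = None,
        fdr: float = 0.10,
        alpha: float = 0.05,
    ) -> list[KMResult]:
        """Analyze every mediator and apply the BH gate across the family."""
        results = []
        for med in self.mediators:
            q = quantiles.get(med) if quantiles else None
            results.append(self.fit(med, quantile=q))
        flags = bh_gate([r.logrank_p for r in results], fdr=fdr, alpha=alpha)
        for r, f in zip(results, flags):
            r.significant = bool(f)
        return results

    def correlations(self) -> pd.DataFrame:
        return pearson_matrix(self.cohort[self.mediators])


# ---------------------------------------------------------------------------
# synthetic cohorts

@dataclass
class HazardSpec:
    """Hazard multiplier applied above a mediator's ``q``-quantile."""

    mediator: str
    q: float
    hr: float


def simulate_cohort(
    n: int,
    hazard_spec: Sequence[HazardSpec] = (),
    censor_rate: float = 0.3,
    seed: int = 0,
    mediators: Sequence[str] = ("IL10", "IL6", "AA"),
    baseline_median_months: float = 24.0,
    mediator_corr: float = 0.0,
    admin_months: float = 60.0,
) -> pd.DataFrame:
    """Simulate a small survival cohort with group-dependent hazards.

    Mediator concentrations are drawn log-normally (optionally equi-
    correlated on the log scale); RFS is exponential with a baseline
    median of ``baseline_median_months``, multiplied by ``hr`` for every
    hazard spec whose mediator exceeds its empirical ``q``-quantile.
    Censoring combines an exponential censoring process calibrated to the
    requested marginal rate with administrative censoring at
    ``admin_months``; ``censor_rate >= 1`` censors everyone.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = len(mediators)
    cov = np.full((k, k), mediator_corr)
    np.fill_diagonal(cov, 1.0)
    logs = rng.multivariate_normal(np.zeros(k), cov, size=n)
    conc = pd.DataFrame(
        np.exp(np.log(100.0) + 1.0 * logs), columns=list(mediators)
    )
    lam0 = math.log(2.0) / baseline_median_months
    lam = np.full(n, lam0)
    for spec in hazard_spec:
        vals = conc[spec.mediator].to_numpy()
        thr = np.quantile(vals, spec.q)
        lam = np.where(vals > thr, lam * spec.hr, lam)
    event_time = rng.exponential(1.0 / lam)
    if censor_rate >= 1.0:
        censor_time = rng.uniform(MIN_FOLLOWUP_MONTHS, admin_months, size=n)
        rfs = censor_time
        event = np.zeros(n, dtype=bool)
    else:
        if censor_rate > 0:
            lam_c = lam0 * censor_rate / (1.0 - censor_rate)
            censor_time = rng.exponential(1.0 / lam_c, size=n)
        else:
            censor_time = np.full(n, np.inf)
        censor_time = np.minimum(censor_time, admin_months)
        event = event_time <= censor_time
        rfs = np.where(event, event_time, censor_time)
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "rfs_months": np.maximum(rfs, 1e-6),
            "event": event,
        }
    )
    return pd.concat([cohort, conc], axis=1)
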
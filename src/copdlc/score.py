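"""Composite lung-cancer susceptibility score and its evaluation.

The score combines a genetic and a clinical component, computed for control
smokers and lung-cancer cases only:

* SNP component — for each scored panel SNP, -1 if the subject carries a
  protective risk genotype, +1 if a susceptible one, 0 otherwise (missing
  genotypes contribute 0). With the default 9-SNP panel (5 protective, 4
  susceptible) the component ranges over [-5, +4].
* clinical component — age > 60 years (+4), family history of lung cancer
  (+3), prior diagnosis of COPD (+4). Pack-years is a recruitment/matching
  variable and never enters the score.

The total score is evaluated by quantile binning (quintiles by default) with
per-bin floated absolute risk (FAR) — log odds relative to a referent bin
with a "floated" variance for every bin including the referent, so that
confidence intervals can be shown for all bins — and by tie-corrected
empirical ROC/AUC.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Contrast, SnpAssociationResults, TwoByTwo, Z95
from .cohort import AnalysisGroup, assign_groups, group_mask, REQUIRED_COLUMNS
from .panel import MISSING, SnpPanelEntry, score_panel

AGE_THRESHOLD = 60  # strict ">": a 60-year-old scores 0 age points
AGE_POINTS = 4
FHX_POINTS = 3
COPD_DX_POINTS = 4


@dataclass(frozen=True)
class ScoreRecord:
    """Per-subject susceptibility score decomposition."""

    subject_id: str
    snp_component: float
    clinical_component: int
    total: float


@dataclass(frozen=True)
class FarEstimate:
    """Floated absolute risk for one score bin."""

    bin_label: str
    n_cases: float
    n_controls: float
    floated_log_risk: float
    floated_variance: float
    ci95: tuple[float, float]  # on the risk-ratio (OR) scale
    is_referent: bool = False
    corrected: bool = False  # Haldane 0.5 applied to this bin's cells


@dataclass(frozen=True)
class RocSummary:
    """Empirical ROC curve and its area."""

    auc: float
    curve: tuple[tuple[float, float], ...]  # (1-specificity, sensitivity)


def snp_component_score(
    genotypes: Mapping[str, str],
    panel: Sequence[SnpPanelEntry],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Cumulative SNP score: sum of direction * [genotype in risk set].

    ``weights`` optionally replaces each SNP's +/-1 direction with a signed
    weight (e.g. a log odds ratio); the unweighted score is the default and
    the published choice — OR-weighting did not improve discrimination.
    """
    total = 0.0
    for entry in score_panel(panel):
        g = genotypes.get(entry.snp_id, MISSING)
        if g == MISSING or g not in entry.alphabet:
            continue
        if g in entry.risk_genotypes:
            w = weights[entry.snp_id] if weights is not None else entry.direction
            total += w
    return total


def clinical_component_score(
    age: float, family_history_lc: bool, prior_copd_dx: bool
) -> int:
    """Weighted clinical score: age>60 (+4), FHx lung cancer (+3), COPD dx (+4).

    A missing (NaN) age contributes 0 age points.
    """
    pts = 0
    if age is not None and not (isinstance(age, float) and math.isnan(age)):
        if age < 0:
            raise ValueError(f"negative age {age}")
        if age > AGE_THRESHOLD:
            pts += AGE_POINTS
    if family_history_lc:
        pts += FHX_POINTS
    if prior_copd_dx:
        pts += COPD_DX_POINTS
    return pts


def susceptibility_score(
    subject, panel: Sequence[SnpPanelEntry],
    weights: Mapping[str, float] | None = None,
) -> ScoreRecord:
    """Total susceptibility score for one :class:`~copdlc.cohort.Subject`."""
    snp = snp_component_score(subject.genotypes, panel, weights=weights)
    clin = clinical_component_score(
        subject.age, subject.family_history_lc, subject.prior_copd_dx
    )
    return ScoreRecord(subject.subject_id, snp, clin, snp + clin)


def compute_scores(
    cohort: pd.DataFrame,
    panel: Sequence[SnpPanelEntry],
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Vectorised scores for a cohort table.

    Returns a frame with columns ``subject_id, snp_component,
    clinical_component, total``.
    """
    snp = pd.Series(0.0, index=cohort.index)
    for entry in score_panel(panel):
        if entry.snp_id not in cohort.columns:
            continue
        w = weights[entry.snp_id] if weights is not None else entry.direction
        snp = snp + cohort[entry.snp_id].isin(entry.risk_genotypes) * float(w)
    age = pd.to_numeric(cohort["age"], errors="coerce")
    clin = (
        (age > AGE_THRESHOLD).fillna(False).astype(int) * AGE_POINTS
        + cohort["family_history_lc"].astype(bool).astype(int) * FHX_POINTS
        + cohort["prior_copd_dx"].astype(bool).astype(int) * COPD_DX_POINTS
    )
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "snp_component": snp,
            "clinical_component": clin,
            "total": snp + clin,
        }
    )


def or_weights_from_battery(
    battery: SnpAssociationResults,
    contrast: Contrast | str = Contrast.LC_VS_CTRL,
) -> dict[str, float]:
    """Signed log-OR weights for the weighted score variant."""
    out = {}
    for entry in score_panel(battery.model.panel):
        try:
            r = battery.get(entry.snp_id, contrast)
        except KeyError:
            continue
        out[entry.snp_id] = math.log(r.odds_ratio)
    return out


# ---------------------------------------------------------------------------
# binning and floated absolute risk


@dataclass(frozen=True)
class BinnedScores:
    """Quantile bins over the pooled score distribution."""

    edges: tuple[float, ...]  # inner edges; len = n_bins - 1
    labels: tuple[str, ...]
    n_cases: tuple[int, ...]
    n_controls: tuple[int, ...]
    assignment: pd.Series  # bin index per subject


def bin_scores(
    totals: pd.Series, is_case: pd.Series, k: int = 5
) -> BinnedScores:
    """Quantile-bin pooled scores into ``k`` groups (quintiles by default).

    Edges come from the pooled (cases + controls) distribution. A score equal
    to an edge goes to the lower bin. When the score distribution has too few
    distinct values, duplicate edges are merged and a warning is issued.
    """
    totals = pd.Series(totals).astype(float)
    if len(totals) < k:
        raise ValueError(f"need at least {k} subjects for {k} bins")
    inner = np.quantile(totals.to_numpy(), [i / k for i in range(1, k)])
    inner = np.unique(inner)
    # drop edges at or below the minimum, which would create empty bins
    inner = inner[inner > totals.min()]
    if len(inner) < k - 1:
        warnings.warn(
            f"only {len(inner) + 1} distinct score bins possible; "
            f"merged from {k}",
            stacklevel=2,
        )
    idx = np.searchsorted(inner, totals.to_numpy(), side="left")
    assignment = pd.Series(idx, index=totals.index)
    nb = len(inner) + 1
    is_case = pd.Series(is_case).astype(bool)
    n_cases = tuple(int(((assignment == b) & is_case).sum()) for b in range(nb))
    n_ctrls = tuple(int(((assignment == b) & ~is_case).sum()) for b in range(nb))
    lo = [-math.inf, *inner]
    hi = [*inner, math.inf]
    labels = tuple(
        f"Q{b + 1} ({'<=' if b < nb - 1 else '>'}"
        f"{hi[b] if b < nb - 1 else lo[b]:g})"
        for b in range(nb)
    )
    return BinnedScores(tuple(inner), labels, n_cases, n_ctrls, assignment)


def _floated_variances(v: np.ndarray, referent: int) -> np.ndarray:
    """Least-squares fit of per-bin floated variances to the covariance
    structure of the bin log-odds contrasts.

    The log odds of bin i relative to the referent r has variance v_i + v_r
    and any two such contrasts share covariance v_r. The floated variances
    s_i^2 are fitted so that Var(L_i - L_j) ~= s_i^2 + s_j^2 for all pairs;
    in this unadjusted polychotomous setting the fit is exact and recovers
    s_i^2 = 1/n_cases_i + 1/n_controls_i for every bin, referent included.
    """
    k = len(v)
    if k == 2:
        return v.copy()
    others = [i for i in range(k) if i != referent]
    rows, y = [], []
    for a_pos, i in enumerate(others):
        row = np.zeros(k)
        row[i] = 1.0
        row[referent] = 1.0
        rows.append(row)
        y.append(v[i] + v[referent])  # Var(L_i)
        for j in others[a_pos + 1:]:
            row = np.zeros(k)
            row[referent] = 1.0
            rows.append(row)
            y.append(v[referent])  # Cov(L_i, L_j)
    s2, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(y), rcond=None)
    return s2


def floated_absolute_risk(
    binned: BinnedScores, referent: int = 0
) -> list[FarEstimate]:
    """Floated absolute risk (FAR) across score bins.

    Each bin's log odds ratio is taken relative to the referent bin, but the
    variance is "floated": every bin, the referent included, receives its own
    variance s_i^2 such that the variance of any between-bin contrast is
    (approximately, here exactly) s_i^2 + s_j^2. Confidence intervals are
    exp(L_i +/- 1.96 s_i). Bins with a zero cell get the Haldane 0.5
    correction and are flagged; a bin empty in both arms is an error.
    """
    a = np.asarray(binned.n_cases, dtype=float)
    b = np.asarray(binned.n_controls, dtype=float)
    k = len(a)
    if k < 2:
        raise ValueError("need at least two bins for FAR")
    if not 0 <= referent < k:
        raise IndexError(f"referent bin {referent} out of range")
    if np.any((a == 0) & (b == 0)):
        raise ValueError("bin empty in both arms")
    corrected = (a == 0) | (b == 0)
    a = np.where(corrected, a + 0.5, a)
    b = np.where(corrected, b + 0.5, b)
    log_odds = np.log(a / b)
    L = log_odds - log_odds[referent]
    v = 1.0 / a + 1.0 / b
    s2 = _floated_variances(v, referent)
    s = np.sqrt(s2)
    return [
        FarEstimate(
            bin_label=binned.labels[i],
            n_cases=binned.n_cases[i],
            n_controls=binned.n_controls[i],
            floated_log_risk=float(L[i]),
            floated_variance=float(s2[i]),
            ci95=(
                float(np.exp(L[i] - Z95 * s[i])),
                float(np.exp(L[i] + Z95 * s[i])),
            ),
            is_referent=(i == referent),
            corrected=bool(corrected[i]),
        )
        for i in range(k)
    ]


def far_contrast_error(far: Sequence[FarEstimate]) -> float:
    """Max relative error of pairwise contrast variances reconstructed from
    floated variances against the direct Woolf variances.

    The diagnostic quoted alongside FAR tables: for bins i, j the direct
    variance of log OR_ij is 1/a_i + 1/b_i + 1/a_j + 1/b_j, to be compared
    with s_i^2 + s_j^2.
    """
    worst = 0.0
    for i, fi in enumerate(far):
        ai = fi.n_cases + (0.5 if fi.corrected else 0.0)
        bi = fi.n_controls + (0.5 if fi.corrected else 0.0)
        for fj in far[i + 1:]:
            aj = fj.n_cases + (0.5 if fj.corrected else 0.0)
            bj = fj.n_controls + (0.5 if fj.corrected else 0.0)
            direct = 1 / ai + 1 / bi + 1 / aj + 1 / bj
            floated = fi.floated_variance + fj.floated_variance
            worst = max(worst, abs(floated - direct) / direct)
    return worst


# ---------------------------------------------------------------------------
# ROC / AUC


def empirical_auc(
    case_scores: Sequence[float], control_scores: Sequence[float]
) -> RocSummary:
    """Tie-corrected empirical AUC and ROC curve.

    AUC is the Mann-Whitney probability that a random case outscores a
    random control, ties counted half — the natural estimator when scores
    are small integers and ties are the norm. The curve thresholds every
    distinct score from high to low.
    """
    cases = np.asarray(case_scores, dtype=float)
    ctrls = np.asarray(control_scores, dtype=float)
    if len(cases) == 0 or len(ctrls) == 0:
        raise ValueError("both score groups must be nonempty")
    pooled = np.concatenate([cases, ctrls])
    ranks = stats.rankdata(pooled)  # mid-ranks handle ties
    r_cases = ranks[: len(cases)].sum()
    m, n = len(cases), len(ctrls)
    auc = (r_cases - m * (m + 1) / 2) / (m * n)
    pts = [(0.0, 0.0)]
    for thr in np.sort(np.unique(pooled))[::-1]:
        tpr = float((cases >= thr).mean())
        fpr = float((ctrls >= thr).mean())
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return RocSummary(auc=float(auc), curve=tuple(pts))


def _hanley_mcneil_var(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    return (
        auc * (1 - auc) + (m - 1) * (q1 - auc * auc) + (n - 1) * (q2 - auc * auc)
    ) / (m * n)


def auc_detection_power(
    n_cases: int,
    n_controls: int,
    auc_alt: float,
    alpha_two_sided: float = 0.05,
) -> float:
    """Normal-approximation power to detect AUC > 0.5 by a two-sided z-test.

    Null variance is the exact Mann-Whitney null (m+n+1)/(12mn); alternative
    variance uses the Hanley-McNeil exponential approximation. Published
    power software uses its own (undisclosed) variance method, so this value
    is cross-validated by :func:`auc_detection_power_mc` rather than against
    any printed figure.
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per arm")
    if not 0.5 < auc_alt < 1:
        raise ValueError("auc_alt must lie in (0.5, 1)")
    m, n = n_cases, n_controls
    se0 = math.sqrt((m + n + 1) / (12 * m * n))
    se1 = math.sqrt(_hanley_mcneil_var(auc_alt, m, n))
    z = stats.norm.ppf(1 - alpha_two_sided / 2)
    delta = auc_alt - 0.5
    return float(
        stats.norm.cdf((delta - z * se0) / se1)
        + stats.norm.cdf((-delta - z * se0) / se1)
    )


def auc_detection_power_mc(
    n_cases: int,
    n_controls: int,
    auc_alt: float,
    alpha_two_sided: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo companion to :func:`auc_detection_power`.

    Simulates binormal scores whose true AUC is ``auc_alt`` (case mean
    sqrt(2) * Phi^-1(AUC)), computes the empirical AUC per replicate and
    applies the same two-sided null z-test.
    """
    if not 0.5 < auc_alt < 1:
        raise ValueError("auc_alt must lie in (0.5, 1)")
    rng = np.random.default_rng(seed)
    delta = math.sqrt(2) * stats.norm.ppf(auc_alt)
    m, n = n_cases, n_controls
    se0 = math.sqrt((m + n + 1) / (12 * m * n))
    z = stats.norm.ppf(1 - alpha_two_sided / 2)
    hits = 0
    for _ in range(n_reps):
        cases = rng.normal(delta, 1.0, m)
        ctrls = rng.normal(0.0, 1.0, n)
        pooled = np.concatenate([cases, ctrls])
        ranks = stats.rankdata(pooled)
        auc = (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
        if abs(auc - 0.5) > z * se0:
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------------------
# model / results objects


class SusceptibilityScoreModel:
    """Composite susceptibility score over control and lung-cancer subjects.

    Only the control-smoker and lung-cancer rows of the cohort enter; COPD
    cases and excluded volunteers are dropped, matching the score's design.

    Parameters
    ----------
    cohort : pandas.DataFrame
        Subject-level cohort table.
    panel : sequence of SnpPanelEntry
        SNP definitions; the scored subset (direction != 0) drives the SNP
        component.
    weights : mapping, optional
        Signed per-SNP weights replacing the +/-1 directions (see
        :func:`or_weights_from_battery`). Default: unweighted.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        panel: Sequence[SnpPanelEntry],
        weights: Mapping[str, float] | None = None,
    ):
        groups = assign_groups(cohort)
        keep = group_mask(groups, AnalysisGroup.CONTROL) | group_mask(
            groups, AnalysisGroup.LC_ALL
        )
        self.cohort = cohort.loc[keep]
        self.groups = groups.loc[keep]
        self.is_case = group_mask(self.groups, AnalysisGroup.LC_ALL)
        self.panel = list(panel)
        self.weights = dict(weights) if weights is not None else None

    def fit(self, n_bins: int = 5, referent: int = 0) -> "SusceptibilityScoreResults":
        scores = compute_scores(self.cohort, self.panel, weights=self.weights)
        scores["group"] = self.groups.values
        scores["is_case"] = self.is_case.values
        binned = bin_scores(scores["total"], scores["is_case"], k=n_bins)
        far = floated_absolute_risk(binned, referent=referent)
        roc = empirical_auc(
            scores.loc[scores["is_case"], "total"],
            scores.loc[~scores["is_case"], "total"],
        )
        return SusceptibilityScoreResults(self, scores, binned, far, roc)


class SusceptibilityScoreResults:
    """Fitted score analysis: per-subject scores, quantile FAR and ROC."""

    def __init__(self, model, scores, binned, far, roc):
        self.model = model
        self.scores = scores
        self.binned = binned
        self.far = far
        self.roc = roc

    @property
    def auc(self) -> float:
        return self.roc.auc

    def far_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": [f.bin_label for f in self.far],
                "n_cases": [f.n_cases for f in self.far],
                "n_controls": [f.n_controls for f in self.far],
                "floated_log_risk": [f.floated_log_risk for f in self.far],
                "floated_variance": [f.floated_variance for f in self.far],
                "or_vs_referent": [math.exp(f.floated_log_risk) for f in self.far],
                "ci95_low": [f.ci95[0] for f in self.far],
                "ci95_high": [f.ci95[1] for f in self.far],
                "referent": [f.is_referent for f in self.far],
            }
        )

    def distribution_frame(self) -> pd.DataFrame:
        """Per-score case/control histogram (score-distribution summary)."""
        tab = (
            self.scores.groupby(["total", "is_case"]).size().unstack(fill_value=0)
        )
        tab = tab.rename(columns={False: "n_controls", True: "n_cases"})
        return tab.reset_index().rename(columns={"total": "score"})

    def summary(self) -> str:
        lines = [
            "Lung-cancer susceptibility score "
            f"({int(self.scores['is_case'].sum())} cases, "
            f"{int((~self.scores['is_case']).sum())} controls)",
            f"AUC = {self.auc:.3f}",
            f"{'bin':<14}{'cases':>7}{'controls':>9}{'OR (FAR)':>10}"
            f"  95% CI",
        ]
        for f in self.far:
            ref = " (referent)" if f.is_referent else ""
            lines.append(
                f"{f.bin_label:<14}{f.n_cases:>7.0f}{f.n_controls:>9.0f}"
                f"{math.exp(f.floated_log_risk):>10.2f}  "
                f"({f.ci95[0]:.2f}-{f.ci95[1]:.2f}){ref}"
            )
        return "\n".join(lines)

    def plot_far(self, ax=None):
        """Score-quantile vs floated-absolute-risk plot (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(self.far))
        y = [math.exp(f.floated_log_risk) for f in self.far]
        lo = [y_i - f.ci95[0] for y_i, f in zip(y, self.far)]
        hi = [f.ci95[1] - y_i for y_i, f in zip(y, self.far)]
        ax.errorbar(x, y, yerr=[lo, hi], fmt="o", capsize=3)
        ax.set_yscale("log")
        ax.set_xticks(x, [f.bin_label for f in self.far], rotation=30)
        ax.set_xlabel("susceptibility-score bin")
        ax.set_ylabel("floated absolute risk (OR)")
        return ax

    def plot_distribution(self, ax=None):
        """Overlaid case/control score distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dist = self.distribution_frame()
        ax.plot(dist["score"], dist["n_controls"] / dist["n_controls"].sum(),
                label="controls", color="tab:blue")
        ax.plot(dist["score"], dist["n_cases"] / dist["n_cases"].sum(),
                label="lung cancer", color="tab:red")
        ax.set_xlabel("susceptibility score")
        ax.set_ylabel("fraction of group")
        ax.legend()
        return ax

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)
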
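"""Case-control association battery for a SNP panel.

Implements the per-SNP QC and association statistics for smoking cohorts
sub-phenotyped for COPD: Hardy-Weinberg equilibrium chi-square, 2x2 odds
ratios with Woolf (log-scale) confidence intervals and Pearson chi-square
p-values under the genotype-collapse and allelic models, Mantel-Haenszel
pooling over strata, the five standard cohort contrasts plus the pooled
"all COPD" contrast, and the heuristic G0-G3 effect-class assignment.

Conventions
-----------
* The "exposed" side of every 2x2 table is the panel entry's risk-genotype
  class (or risk allele), so odds ratios are oriented exactly as tabulated.
* P-values are Pearson chi-square on 1 df without continuity correction.
* Zero cells: with ``correction="haldane"`` (the battery default) 0.5 is
  added to all four cells before OR, CI and chi-square whenever any cell is
  zero, and the result is flagged.
* No multiple-testing correction is applied: the panel SNPs are chosen a
  priori from genome-wide studies.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as _cohort
from .cohort import AnalysisGroup, assign_groups, group_mask, snp_call_rate
from .panel import MISSING, SnpPanelEntry

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateTableError(ValueError):
    """2x2 table unusable (zero margin, or zero cell without correction)."""


class Contrast(str, enum.Enum):
    """The cohort contrasts of the association battery.

    Each value maps a (case-group, control-group) pair;
    ``COMBINED_COPD_VS_CTRL`` pools the COPD cases with the lung-cancer
    cases who also meet GOLD 2+ criteria.
    """

    COPD_VS_CTRL = "COPD_VS_CTRL"
    LC_VS_CTRL = "LC_VS_CTRL"
    LCCOPD_VS_CTRL = "LCCOPD_VS_CTRL"
    LCONLY_VS_CTRL = "LCONLY_VS_CTRL"
    LCCOPD_VS_LCONLY = "LCCOPD_VS_LCONLY"
    COMBINED_COPD_VS_CTRL = "COMBINED_COPD_VS_CTRL"


#: case / reference analysis groups per contrast (COMBINED handled apart)
_CONTRAST_GROUPS: dict[Contrast, tuple[AnalysisGroup, AnalysisGroup]] = {
    Contrast.COPD_VS_CTRL: (AnalysisGroup.COPD, AnalysisGroup.CONTROL),
    Contrast.LC_VS_CTRL: (AnalysisGroup.LC_ALL, AnalysisGroup.CONTROL),
    Contrast.LCCOPD_VS_CTRL: (AnalysisGroup.LC_WITH_COPD, AnalysisGroup.CONTROL),
    Contrast.LCONLY_VS_CTRL: (AnalysisGroup.LC_ONLY, AnalysisGroup.CONTROL),
    Contrast.LCCOPD_VS_LCONLY: (AnalysisGroup.LC_WITH_COPD, AnalysisGroup.LC_ONLY),
}


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-status contingency table."""

    case_exposed: float
    case_unexposed: float
    ctrl_exposed: float
    ctrl_unexposed: float

    def __post_init__(self) -> None:
        cells = self.cells
        if any(c < 0 for c in cells):
            raise ValueError("negative cell count")
        if sum(cells) <= 0:
            raise ValueError("empty 2x2 table")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (
            self.case_exposed,
            self.case_unexposed,
            self.ctrl_exposed,
            self.ctrl_unexposed,
        )

    @property
    def n(self) -> float:
        return sum(self.cells)


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg equilibrium goodness-of-fit (1 df)."""

    chi2: float
    p_value: float
    minor_allele_freq: float


@dataclass(frozen=True)
class AssociationResult:
    """One SNP x contrast x model association estimate."""

    snp_id: str
    comparison: Contrast
    model: str  # "GENOTYPE_COLLAPSE" or "ALLELIC"
    table: TwoByTwo
    odds_ratio: float
    ci95: tuple[float, float]
    chi2: float
    p_value: float
    corrected: bool = False  # Haldane 0.5 applied
    exposure: str = ""  # e.g. "CC" or "TT/TC" or allele letter


def hwe_chi_square(n_hom_major: int, n_het: int, n_hom_minor: int) -> HweResult:
    """Pearson goodness-of-fit test of Hardy-Weinberg proportions.

    Allele frequencies are estimated from the genotype counts; expected
    counts are n*p^2, 2npq, n*q^2 and the statistic is referred to a
    chi-square with one degree of freedom (alleles estimated from the data).
    """
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("no genotype calls")
    p = (2 * n_hom_major + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    chi2 = float(np.nansum(np.where(expected > 0, terms, 0.0)))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p_value=pval, minor_allele_freq=min(p, q))


def _pearson_chi2(t: TwoByTwo) -> float:
    a, b, c, d = t.cells
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        raise DegenerateTableError("zero margin in 2x2 table")
    return n * (a * d - b * c) ** 2 / denom


def odds_ratio_2x2(
    t: TwoByTwo, correction: str = "haldane"
) -> tuple[float, tuple[float, float], float, float, bool]:
    """Odds ratio with Woolf 95% CI and Pearson chi-square p for a 2x2 table.

    OR = (case_exposed * ctrl_unexposed) / (case_unexposed * ctrl_exposed);
    CI = exp(ln OR +/- 1.96 * sqrt(sum of reciprocal cells)). With
    ``correction="haldane"`` and any zero cell, 0.5 is added to all four
    cells before all three computations; with ``correction="none"`` a zero
    cell raises :class:`DegenerateTableError`.

    Returns ``(odds_ratio, (lo, hi), chi2, p_value, corrected)``.
    """
    if correction not in ("haldane", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    corrected = False
    if any(c == 0 for c in t.cells):
        if correction == "none":
            raise DegenerateTableError("zero cell; odds ratio undefined")
        t = TwoByTwo(*(c + 0.5 for c in t.cells))
        corrected = True
    a, b, c, d = t.cells
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(oratio) - Z95 * se), math.exp(math.log(oratio) + Z95 * se)
    chi2 = _pearson_chi2(t)
    p = float(stats.chi2.sf(chi2, df=1))
    return oratio, (lo, hi), chi2, p, corrected


def genotype_collapse(
    counts_by_genotype: Mapping[str, int], exposed_set: Sequence[str] | frozenset[str]
) -> tuple[int, int]:
    """Collapse genotype counts to (exposed, unexposed) for a 2x2 contrast."""
    exposed_set = set(exposed_set)
    alphabet = set(counts_by_genotype)
    if not exposed_set or not exposed_set < alphabet:
        raise ValueError(
            f"exposed set {sorted(exposed_set)} must be a nonempty strict "
            f"subset of {sorted(alphabet)}"
        )
    exposed = sum(counts_by_genotype[g] for g in exposed_set)
    unexposed = sum(counts_by_genotype[g] for g in alphabet - exposed_set)
    return exposed, unexposed


def allele_counts(
    counts_by_genotype: Mapping[str, int], allele: str
) -> tuple[int, int]:
    """Expand genotype counts to (allele, other-allele) chromosome counts."""
    carrying = other = 0
    for geno, n in counts_by_genotype.items():
        k = geno.count(allele)
        carrying += k * n
        other += (len(geno) - k) * n
    return carrying, other


def allele_2x2(
    counts_cases: Mapping[str, int],
    counts_controls: Mapping[str, int],
    risk_allele: str,
    correction: str = "haldane",
) -> tuple[TwoByTwo, float, tuple[float, float], float, float, bool]:
    """Additive (allelic) model: 2x2 on allele counts, risk allele exposed."""
    ce, cu = allele_counts(counts_cases, risk_allele)
    ke, ku = allele_counts(counts_controls, risk_allele)
    t = TwoByTwo(ce, cu, ke, ku)
    return (t, *odds_ratio_2x2(t, correction=correction))


def mantel_haenszel(strata: Sequence[TwoByTwo]) -> tuple[float, float, float]:
    """Mantel-Haenszel pooled odds ratio and 1-df MH chi-square over strata.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the chi-square compares
    the summed exposed-case counts to their conditional expectations (no
    continuity correction). Returns ``(or_mh, chi2, p)``.
    """
    if not strata:
        raise ValueError("no strata")
    num = den = 0.0
    a_sum = e_sum = v_sum = 0.0
    for t in strata:
        a, b, c, d = t.cells
        n = t.n
        num += a * d / n
        den += b * c / n
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        a_sum += a
        e_sum += r1 * c1 / n
        if n > 1:
            v_sum += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if den == 0 or v_sum == 0:
        raise DegenerateTableError("all strata degenerate for MH pooling")
    or_mh = num / den
    chi2 = (a_sum - e_sum) ** 2 / v_sum
    p = float(stats.chi2.sf(chi2, df=1))
    return or_mh, chi2, p


def genotype_counts_by_group(
    cohort: pd.DataFrame,
    panel: Sequence[SnpPanelEntry],
    groups: pd.Series | None = None,
) -> dict[str, dict[str, dict[str, int]]]:
    """Per-SNP, per-analysis-group genotype counts (missing calls dropped).

    Keys: snp_id -> group value -> genotype -> count, with the overlapping
    groups (LC_ALL, the COMBINED pool) materialised explicitly.
    """
    if groups is None:
        groups = assign_groups(cohort)
    masks = {
        g.value: group_mask(groups, g)
        for g in (
            AnalysisGroup.CONTROL,
            AnalysisGroup.COPD,
            AnalysisGroup.LC_ALL,
            AnalysisGroup.LC_WITH_COPD,
            AnalysisGroup.LC_ONLY,
        )
    }
    masks["COMBINED_COPD"] = masks[AnalysisGroup.COPD.value] | masks[
        AnalysisGroup.LC_WITH_COPD.value
    ]
    out: dict[str, dict[str, dict[str, int]]] = {}
    for entry in panel:
        if entry.snp_id not in cohort.columns:
            continue
        col = cohort[entry.snp_id]
        out[entry.snp_id] = {
            gname: {
                g: int(((col == g) & mask).sum()) for g in entry.alphabet
            }
            for gname, mask in masks.items()
        }
    return out


def _contrast_counts(
    counts: dict[str, dict[str, int]], contrast: Contrast
) -> tuple[dict[str, int], dict[str, int]]:
    if contrast is Contrast.COMBINED_COPD_VS_CTRL:
        return counts["COMBINED_COPD"], counts[AnalysisGroup.CONTROL.value]
    case_g, ref_g = _CONTRAST_GROUPS[contrast]
    return counts[case_g.value], counts[ref_g.value]


def association_battery(
    cohort: pd.DataFrame,
    panel: Sequence[SnpPanelEntry],
    alpha: float = 0.05,
    models: Sequence[str] = ("GENOTYPE_COLLAPSE", "ALLELIC"),
    groups: pd.Series | None = None,
) -> dict[str, list[AssociationResult]]:
    """Run every contrast x model for every panel SNP present in the cohort.

    The exposed class of each 2x2 is the panel's risk-genotype set (genotype
    model) or risk allele (allelic model). Empty analysis groups raise.
    """
    if groups is None:
        groups = assign_groups(cohort)
    for g in (AnalysisGroup.CONTROL, AnalysisGroup.COPD, AnalysisGroup.LC_ALL):
        if not group_mask(groups, g).any():
            raise _cohort.CohortValidationError(f"analysis group {g.value} is empty")
    counts_all = genotype_counts_by_group(cohort, panel, groups=groups)
    results: dict[str, list[AssociationResult]] = {}
    for entry in panel:
        if entry.snp_id not in counts_all:
            continue
        counts = counts_all[entry.snp_id]
        res: list[AssociationResult] = []
        for contrast in Contrast:
            case_counts, ref_counts = _contrast_counts(counts, contrast)
            if sum(case_counts.values()) == 0 or sum(ref_counts.values()) == 0:
                continue
            if "GENOTYPE_COLLAPSE" in models:
                ce, cu = genotype_collapse(case_counts, entry.risk_genotypes)
                ke, ku = genotype_collapse(ref_counts, entry.risk_genotypes)
                t = TwoByTwo(ce, cu, ke, ku)
                oratio, ci, chi2, p, corr = odds_ratio_2x2(t)
                exposed_lbl = "/".join(
                    g for g in entry.alphabet if g in entry.risk_genotypes
                )
                res.append(
                    AssociationResult(
                        entry.snp_id, contrast, "GENOTYPE_COLLAPSE", t,
                        oratio, ci, chi2, p, corr, exposed_lbl,
                    )
                )
            if "ALLELIC" in models and entry.risk_allele:
                t, oratio, ci, chi2, p, corr = allele_2x2(
                    case_counts, ref_counts, entry.risk_allele
                )
                res.append(
                    AssociationResult(
                        entry.snp_id, contrast, "ALLELIC", t,
                        oratio, ci, chi2, p, corr, entry.risk_allele,
                    )
                )
        results[entry.snp_id] = res
    return results


def classify_effect_group(
    results: Sequence[AssociationResult], alpha: float = 0.05
) -> str:
    """Heuristic G0-G3 effect class from the genotype-model contrast pattern.

    A contrast "hits" when its genotype-model p-value is below ``alpha``;
    direction is the side of 1 its OR falls on. Precedence:

    * G0 — protective hit vs COPD *and* a protective hit vs a lung-cancer
      contrast (either sub-phenotype): protects against both diseases.
    * G2 — susceptible hit in a COPD-containing contrast (COPD or
      LC-with-COPD): susceptibility involving COPD (and typically lung
      cancer in its presence).
    * G1 — hit only vs COPD: a COPD-specific effect.
    * G3 — hit only in the LC-without-COPD contrast: lung cancer only.
    * UNASSIGNED otherwise.

    The published class labels follow this pattern for eight of the nine
    scored SNPs; the rule is a reconstruction, not a published algorithm.
    """
    by_contrast = {
        r.comparison: r
        for r in results
        if r.model == "GENOTYPE_COLLAPSE"
    }

    def hit(c: Contrast) -> int:
        r = by_contrast.get(c)
        if r is None or r.p_value >= alpha:
            return 0
        return 1 if r.odds_ratio > 1 else -1

    h_copd = hit(Contrast.COPD_VS_CTRL)
    h_lccopd = hit(Contrast.LCCOPD_VS_CTRL)
    h_lconly = hit(Contrast.LCONLY_VS_CTRL)
    if h_copd == -1 and (h_lccopd == -1 or h_lconly == -1):
        return "G0"
    if h_copd == 1 or h_lccopd == 1:
        return "G2"
    if h_copd != 0 and h_lccopd == 0 and h_lconly == 0:
        return "G1"
    if h_lconly != 0 and h_copd == 0 and h_lccopd == 0:
        return "G3"
    return "UNASSIGNED"


# ---------------------------------------------------------------------------
# model / results objects


class SnpAssociationModel:
    """Case-control SNP association battery over a sub-phenotyped cohort.

    Parameters
    ----------
    cohort : pandas.DataFrame
        Subject-level table as produced by
        :func:`copdlc.cohort.read_cohort_table` or the synthetic generator.
    panel : sequence of SnpPanelEntry
        SNP definitions; only SNPs with a genotype column present are used.

    Examples
    --------
    >>> from copdlc import SnpAssociationModel, default_panel, table_fixture
    >>> res = SnpAssociationModel(table_fixture(), default_panel()).fit()
    >>> round(res.odds_ratio("rs7671167", "LC_VS_CTRL"), 2)
    0.64
    """

    def __init__(self, cohort: pd.DataFrame, panel: Sequence[SnpPanelEntry]):
        self.cohort = cohort
        self.panel = list(panel)
        self.groups = assign_groups(cohort)

    def fit(
        self,
        alpha: float = 0.05,
        models: Sequence[str] = ("GENOTYPE_COLLAPSE", "ALLELIC"),
    ) -> "SnpAssociationResults":
        results = association_battery(
            self.cohort, self.panel, alpha=alpha, models=models, groups=self.groups
        )
        counts = genotype_counts_by_group(self.cohort, self.panel, groups=self.groups)
        hwe_rows = []
        for entry in self.panel:
            if entry.snp_id not in counts:
                continue
            for gname, c in counts[entry.snp_id].items():
                triple = [c[g] for g in entry.alphabet]
                if sum(triple) == 0:
                    continue
                h = hwe_chi_square(*triple)
                hwe_rows.append(
                    {
                        "snp_id": entry.snp_id,
                        "group": gname,
                        "chi2": h.chi2,
                        "p_value": h.p_value,
                        "maf": h.minor_allele_freq,
                    }
                )
        qc_rows = []
        for entry in self.panel:
            if entry.snp_id not in counts:
                continue
            cr = snp_call_rate(self.cohort, entry.snp_id, groups=self.groups)
            cr.insert(0, "snp_id", entry.snp_id)
            qc_rows.append(cr)
        effect = {
            snp: classify_effect_group(res, alpha=alpha)
            for snp, res in results.items()
        }
        return SnpAssociationResults(
            model=self,
            alpha=alpha,
            results=results,
            genotype_counts=counts,
            hwe=pd.DataFrame(hwe_rows),
            call_rates=pd.concat(qc_rows, ignore_index=True)
            if qc_rows
            else pd.DataFrame(),
            effect_classes=effect,
        )


class SnpAssociationResults:
    """Fitted association battery: estimates, QC tables and summaries."""

    def __init__(
        self,
        model: SnpAssociationModel,
        alpha: float,
        results: dict[str, list[AssociationResult]],
        genotype_counts: dict,
        hwe: pd.DataFrame,
        call_rates: pd.DataFrame,
        effect_classes: dict[str, str],
    ):
        self.model = model
        self.alpha = alpha
        self.results = results
        self.genotype_counts = genotype_counts
        self.hwe = hwe
        self.call_rates = call_rates
        self.effect_classes = effect_classes

    def get(
        self,
        snp_id: str,
        contrast: Contrast | str,
        model: str = "GENOTYPE_COLLAPSE",
    ) -> AssociationResult:
        contrast = Contrast(contrast)
        for r in self.results.get(snp_id, []):
            if r.comparison is contrast and r.model == model:
                return r
        raise KeyError(f"no result for {snp_id} {contrast.value} {model}")

    def odds_ratio(
        self,
        snp_id: str,
        contrast: Contrast | str,
        model: str = "GENOTYPE_COLLAPSE",
    ) -> float:
        return self.get(snp_id, contrast, model).odds_ratio

    def frame(self) -> pd.DataFrame:
        """All estimates as a tidy frame (fixed, documented column order)."""
        rows = []
        for snp, lst in self.results.items():
            for r in lst:
                a, b, c, d = r.table.cells
                rows.append(
                    {
                        "snp_id": snp,
                        "contrast": r.comparison.value,
                        "model": r.model,
                        "exposure": r.exposure,
                        "case_exposed": a,
                        "case_unexposed": b,
                        "ctrl_exposed": c,
                        "ctrl_unexposed": d,
                        "odds_ratio": r.odds_ratio,
                        "ci95_low": r.ci95[0],
                        "ci95_high": r.ci95[1],
                        "chi2": r.chi2,
                        "p_value": r.p_value,
                        "haldane_corrected": r.corrected,
                        "effect_class": self.effect_classes.get(snp, "UNASSIGNED"),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable battery summary (genotype model only)."""
        df = self.frame()
        df = df[df["model"] == "GENOTYPE_COLLAPSE"]
        lines = [
            "SNP association battery "
            f"(alpha={self.alpha}, {len(self.results)} SNPs)",
            f"{'snp':<12}{'contrast':<24}{'OR':>6}  {'95% CI':<16}"
            f"{'p':>8}  class",
        ]
        for _, r in df.iterrows():
            ci = f"({r.ci95_low:.2f}-{r.ci95_high:.2f})"
            lines.append(
                f"{r.snp_id:<12}{r.contrast:<24}{r.odds_ratio:>6.2f}  "
                f"{ci:<16}{r.p_value:>8.3g}  {r.effect_class}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)
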
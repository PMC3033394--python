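"""Synthetic smoking-matched cohorts.

Two sources of subject-level data are provided:

* :func:`table_fixture` — a deterministic cohort whose per-group, per-SNP
  genotype counts equal the published genotype-frequency table of the study
  this package models (control smokers, COPD cases, and lung-cancer cases
  sub-phenotyped for COPD), with clinical covariates laid on at the
  published marginal prevalences. Genotype columns are filled independently
  per SNP, so between-SNP and genotype-covariate joint structure is NOT that
  of the real study — the fixture reproduces exactly the quantities
  computable from printed marginals (counts, odds ratios, HWE) and nothing
  more.
* :func:`sample_cohort` — a seeded random generator over a
  :class:`GeneratorSpec` (per-group sizes, per-SNP genotype probability
  triples, clinical prevalences, optional pairwise genotype concordance),
  used for null checks, parameter-recovery tests and power experiments.

Known blemishes of the printed table are honoured rather than repaired: the
per-SNP column sums differ from the cohort headcounts (call-rate variation;
the shortfall becomes missing calls), one column sums above its headcount,
and one SNP's whole-cohort column is incompatible with its sub-phenotype
columns and cannot be reproduced subject-level (see the fixture notes in
the package documentation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import REQUIRED_COLUMNS
from .panel import MISSING, SnpPanelEntry, default_panel

#: published genotype counts per SNP per analysis group, in each SNP's
#: alphabet order (major-hom, het, minor-hom as tabulated)
TABLE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "rs2808630": {  # CRP, TT/TC/CC
        "control": (225, 205, 53), "copd": (214, 197, 35),
        "lc": (214, 193, 34), "lc_copd": (99, 90, 18), "lc_only": (106, 85, 11),
    },
    "rs7671167": {  # FAM13A, CC/TC/TT
        "control": (145, 240, 100), "copd": (107, 234, 117),
        "lc": (96, 235, 118), "lc_copd": (47, 118, 50), "lc_only": (41, 103, 63),
    },
    "rs10516526": {  # GSTCD, AA/AG/GG
        "control": (409, 69, 1), "copd": (394, 61, 2),
        "lc": (381, 63, 0), "lc_copd": (178, 37, 0), "lc_only": (180, 23, 0),
    },
    "rs1489759": {  # HHIP, AA/AG/GG
        "control": (178, 223, 83), "copd": (187, 220, 50),
        "lc": (174, 215, 56), "lc_copd": (103, 86, 24), "lc_only": (97, 82, 27),
    },
    "rs2202507": {  # GYPA, AA/AC/CC
        "control": (138, 213, 129), "copd": (136, 233, 88),
        "lc": (116, 233, 90), "lc_copd": (62, 107, 43), "lc_only": (52, 113, 39),
    },
    "rs402710": {  # CRR9/TERT, GG/GA/AA
        "control": (216, 230, 41), "copd": (200, 206, 52),
        "lc": (212, 198, 43), "lc_copd": (90, 106, 19), "lc_only": (109, 77, 21),
    },
    "rs11168048": {  # HTR4, TT/CT/CC
        "control": (160, 228, 98), "copd": (153, 216, 89),
        "lc": (155, 209, 88), "lc_copd": (80, 95, 40), "lc_only": (61, 101, 45),
    },
    "rs1422795": {  # ADAM19, TT/CT/CC
        "control": (213, 227, 46), "copd": (189, 207, 59),
        "lc": (183, 210, 58), "lc_copd": (86, 100, 29), "lc_only": (84, 96, 26),
    },
    "rs1052486": {  # BAT3, AA/AG/GG
        "control": (119, 239, 108), "copd": (127, 222, 93),
        "lc": (112, 210, 116), "lc_copd": (51, 93, 65), "lc_only": (55, 105, 43),
    },
    "rs2070600": {  # AGER, CC/CT/TT
        "control": (412, 70, 3), "copd": (413, 41, 3),
        "lc": (388, 58, 2), "lc_copd": (185, 29, 1), "lc_only": (175, 28, 1),
    },
    "rs11155242": {  # GPR126, AA/AC/CC
        "control": (298, 161, 14), "copd": (290, 147, 14),
        "lc": (287, 147, 11), "lc_copd": (141, 69, 3), "lc_only": (128, 69, 8),
    },
    "rs16969968": {  # CHRNA3/5, GG/GA/AA
        "control": (225, 205, 45), "copd": (166, 219, 60),
        "lc": (170, 199, 68), "lc_copd": (86, 125, 50), "lc_only": (81, 69, 18),
    },
}

#: fixture group sizes, driven by the largest per-SNP column sum of each
#: group (the whole-cohort LC column is topped up through 32 lung-cancer
#: subjects without usable spirometry)
FIXTURE_GROUP_SIZES = {
    "control": 488,
    "copd": 458,
    "lc_copd": 261,
    "lc_only": 207,
    "lc_nospiro": 32,
}

#: published clinical marginals per primary cohort; age>60 fractions derive
#: from the printed normal age summaries (mean 65/66/69, SD 10/9/10)
CLINICAL_MARGINALS = {
    "control": {"age_gt60": 0.69, "fhx_lc": 0.09, "prior_copd_dx": 0.00, "male": 0.60},
    "copd": {"age_gt60": 0.75, "fhx_lc": 0.11, "prior_copd_dx": 1.00, "male": 0.59},
    "lc": {"age_gt60": 0.82, "fhx_lc": 0.19, "prior_copd_dx": 0.51, "male": 0.53},
}

#: group-typical pre-bronchodilator spirometry (FEV1 %pred, FEV1/FVC %) and
#: pack-years used for deterministic fixture rows
_FIXTURE_PHYSIO = {
    "control": (99.0, 78.0, 40.0),
    "copd": (46.0, 46.0, 47.0),
    "lc_copd": (60.0, 55.0, 41.0),
    "lc_only": (85.0, 75.0, 41.0),
    "lc_nospiro": (math.nan, math.nan, 41.0),
}

_GROUP_LABEL = {
    "control": "CONTROL_VOLUNTEER",
    "copd": "COPD_CASE",
    "lc_copd": "LUNG_CANCER_CASE",
    "lc_only": "LUNG_CANCER_CASE",
    "lc_nospiro": "LUNG_CANCER_CASE",
}

_GROUP_PREFIX = {
    "control": "CT",
    "copd": "CP",
    "lc_copd": "LCC",
    "lc_only": "LCO",
    "lc_nospiro": "LCX",
}

_CLINICAL_KEY = {
    "control": "control",
    "copd": "copd",
    "lc_copd": "lc",
    "lc_only": "lc",
    "lc_nospiro": "lc",
}


class InfeasibleSpecError(ValueError):
    """Generator spec cannot be realised (e.g. concordance target)."""


# ---------------------------------------------------------------------------
# deterministic fixture


def _spread_positions(n: int, k: int, phase: int) -> np.ndarray:
    """k evenly spread, distinct slot indices out of n (deterministic)."""
    if k <= 0:
        return np.empty(0, dtype=int)
    base = (np.arange(k) * n) // k
    return (base + phase) % n


def _spread_flags(n: int, fraction: float, phase: int) -> np.ndarray:
    k = int(math.floor(n * fraction + 0.5))
    flags = np.zeros(n, dtype=bool)
    flags[_spread_positions(n, min(k, n), phase)] = True
    return flags


def _fill_genotypes(
    n: int, counts: Sequence[int], alphabet: Sequence[str], offset: int
) -> np.ndarray:
    """Assign genotype counts to n slots in rotated slot order; rest NN."""
    if sum(counts) > n:
        raise ValueError(f"counts {counts} exceed {n} slots")
    order = (np.arange(n) + offset) % n
    col = np.full(n, MISSING, dtype=object)
    pos = 0
    for geno, c in zip(alphabet, counts):
        col[order[pos:pos + c]] = geno
        pos += c
    return col


def table_fixture(panel: Sequence[SnpPanelEntry] | None = None) -> pd.DataFrame:
    """Deterministic cohort reproducing the published genotype counts.

    Per SNP and analysis-group column the genotype counts equal the printed
    table exactly; slots left over by per-SNP call-rate variation hold the
    missing sentinel. The whole-cohort lung-cancer column is recovered by
    adding the count shortfall (printed LC column minus the two
    sub-phenotype columns) to lung-cancer subjects without spirometry; for
    the one SNP whose printed LC column is smaller than the sum of its
    sub-phenotype columns this is impossible and the sub-phenotype columns
    win. Clinical covariates follow the published marginal prevalences via
    largest-remainder rounding, spread deterministically and independently
    of genotype. Byte-identical across runs.
    """
    if panel is None:
        panel = default_panel()
    frames = []
    for gi, (group, n) in enumerate(FIXTURE_GROUP_SIZES.items()):
        clin = CLINICAL_MARGINALS[_CLINICAL_KEY[group]]
        pct, ratio, pky = _FIXTURE_PHYSIO[group]
        age_flag = _spread_flags(n, clin["age_gt60"], phase=0)
        fhx = _spread_flags(n, clin["fhx_lc"], phase=13)
        # prior COPD diagnosis proxied by spirometric COPD status; the
        # published whole-LC prevalence applies to spirometry-missing cases
        dx_frac = {"control": 0.0, "copd": 1.0, "lc_copd": 1.0,
                   "lc_only": 0.0, "lc_nospiro": clin["prior_copd_dx"]}[group]
        copd_dx = _spread_flags(n, dx_frac, phase=26)
        male = _spread_flags(n, clin["male"], phase=39)
        df = pd.DataFrame(
            {
                "subject_id": [
                    f"FX-{_GROUP_PREFIX[group]}{i:04d}" for i in range(n)
                ],
                "disease_label": _GROUP_LABEL[group],
                "age": np.where(age_flag, 70, 50),
                "sex": np.where(male, "M", "F"),
                "fev1_pct_pred": pct,
                "fev1_fvc": ratio,
                "pack_years": pky,
                "family_history_lc": fhx,
                "prior_copd_dx": copd_dx,
            }
        )
        for si, entry in enumerate(panel):
            counts = TABLE_COUNTS[entry.snp_id]
            if group == "lc_nospiro":
                short = [
                    max(counts["lc"][j] - counts["lc_copd"][j] - counts["lc_only"][j], 0)
                    for j in range(3)
                ]
                # cap at available slots, filling in alphabet order
                capped, left = [], n
                for s in short:
                    take = min(s, left)
                    capped.append(take)
                    left -= take
                fill = capped
            else:
                fill = counts[group]
            df[entry.snp_id] = _fill_genotypes(
                n, fill, entry.alphabet, offset=(si * 29 + gi * 7) % n
            )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["age"] = out["age"].astype(int)
    return out


# ---------------------------------------------------------------------------
# random generator


@dataclass
class GeneratorSpec:
    """Conditions for a synthetic smoking-matched cohort.

    Parameters
    ----------
    group_sizes : mapping
        Subject counts for ``control, copd, lc_copd, lc_only`` (and
        optionally ``lc_nospiro``).
    genotype_probs : mapping
        ``snp_id -> group -> (p_majorhom, p_het, p_minorhom)``; triples must
        sum to 1.
    clinical : mapping
        ``control/copd/lc -> {age_gt60, fhx_lc, prior_copd_dx, male}``
        prevalences.
    concordance : mapping, optional
        ``(snp_a, snp_b) -> target genotype-agreement fraction`` for SNP
        pairs in linkage disequilibrium; both SNPs' marginals are preserved
        exactly while the joint draw hits the target agreement in
        expectation.
    seed : int
        Default seed for :func:`sample_cohort`.
    """

    group_sizes: dict[str, int]
    genotype_probs: dict[str, dict[str, tuple[float, float, float]]]
    clinical: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CLINICAL_MARGINALS.items()}
    )
    concordance: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for snp, per_group in self.genotype_probs.items():
            for g, triple in per_group.items():
                if len(triple) != 3 or abs(sum(triple) - 1.0) > 1e-6:
                    raise InfeasibleSpecError(
                        f"{snp}/{g}: genotype probabilities {triple} must sum to 1"
                    )
        for pair, t in self.concordance.items():
            if not 0.0 <= t <= 1.0:
                raise InfeasibleSpecError(f"concordance target {pair}: {t}")


def _table_probs(column: str = "subgroup") -> dict[str, dict[str, tuple]]:
    probs: dict[str, dict[str, tuple]] = {}
    for snp, counts in TABLE_COUNTS.items():
        per_group = {}
        for g in ("control", "copd", "lc_copd", "lc_only"):
            c = np.asarray(counts[g], dtype=float)
            per_group[g] = tuple(c / c.sum())
        probs[snp] = per_group
    return probs


def table_spec(
    n_per_group: int | None = None,
    seed: int = 0,
    concordance: Mapping[tuple[str, str], float] | None = None,
) -> GeneratorSpec:
    """Generator spec plugged in from the published genotype frequencies.

    Default sizes are the published group sizes; pass ``n_per_group`` to
    scale every group to a common size (e.g. for parameter-recovery runs).
    The HHIP/GYPA pair on 4q31 is given its published 65% genotype
    concordance unless overridden.
    """
    sizes = {"control": 488, "copd": 458, "lc_copd": 215, "lc_only": 207}
    if n_per_group is not None:
        sizes = {g: n_per_group for g in sizes}
    conc = (
        {("rs1489759", "rs2202507"): 0.65}
        if concordance is None
        else dict(concordance)
    )
    return GeneratorSpec(
        group_sizes=sizes,
        genotype_probs=_table_probs(),
        concordance=conc,
        seed=seed,
    )


def _joint_genotype_probs(
    p: np.ndarray, q: np.ndarray, target: float
) -> np.ndarray:
    """3x3 joint distribution with marginals p, q and diagonal mass target.

    Mixes the independent coupling with a maximal-agreement coupling:
    J(lam) = lam * diag(min(p, q)) + r c^T / (1 - lam * S), where
    r = p - lam*min, c = q - lam*min, S = sum(min(p, q)). Marginals hold for
    every lam in [0, 1]; agreement rises monotonically from sum(p*q) at
    lam=0 to S at lam=1. lam is solved for the target agreement.
    """
    m = np.minimum(p, q)
    s = m.sum()

    def joint(lam: float) -> np.ndarray:
        r = p - lam * m
        c = q - lam * m
        denom = 1.0 - lam * s
        out = np.outer(r, c) / denom if denom > 1e-12 else np.zeros((3, 3))
        out[np.diag_indices(3)] += lam * m
        return out

    def agreement(lam: float) -> float:
        return float(np.trace(joint(lam)))

    lo, hi = agreement(0.0), agreement(1.0)
    if not lo - 1e-9 <= target <= hi + 1e-9:
        raise InfeasibleSpecError(
            f"concordance target {target:.3f} outside feasible range "
            f"[{lo:.3f}, {hi:.3f}] for the given marginals"
        )
    lam = optimize.brentq(lambda x: agreement(x) - target, 0.0, 1.0)
    return joint(lam)


def _sample_spirometry(
    rng: np.random.Generator, group: str, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Spirometry draws guaranteed to classify into the intended group."""
    if group == "lc_nospiro":
        return np.full(n, np.nan), np.full(n, np.nan)
    if group in ("copd", "lc_copd"):
        pct = np.clip(rng.normal(50, 14, n), 15, 80.0)
        ratio = np.clip(rng.normal(48, 8, n), 25, 69.5)
    elif group == "control":
        pct = np.clip(rng.normal(99, 13, n), 60, 140)
        ratio = np.clip(rng.normal(78, 6, n), 70.0, 95)
    else:  # lc_only: lung cancer free of GOLD-2+ obstruction
        pct = np.clip(rng.normal(85, 12, n), 50, 140)
        ratio = np.clip(rng.normal(74, 4, n), 70.0, 95)
    return np.round(pct, 1), np.round(ratio, 1)


def sample_cohort(
    spec: GeneratorSpec,
    seed: int | None = None,
    panel: Sequence[SnpPanelEntry] | None = None,
) -> pd.DataFrame:
    """Draw a seeded synthetic cohort from a :class:`GeneratorSpec`.

    Genotypes are drawn independently per SNP from each group's probability
    triple, except concordance-constrained pairs which are drawn jointly.
    Pack-years comes from a common distribution across groups (the cohorts
    are smoking-matched by design); spirometry is drawn so the intended
    analysis-group labels are recovered exactly by classification.
    """
    spec.validate()
    if panel is None:
        panel = default_panel()
    by_id = {e.snp_id: e for e in panel}
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    paired: dict[str, tuple[str, float, bool]] = {}
    for (a, b), t in spec.concordance.items():
        paired[a] = (b, t, True)
        paired[b] = (a, t, False)
    frames = []
    for group, n in spec.group_sizes.items():
        if n <= 0:
            continue
        clin = spec.clinical[_CLINICAL_KEY[group]]
        age_flag = rng.random(n) < clin["age_gt60"]
        age = np.where(
            age_flag,
            np.clip(np.round(61 + np.abs(rng.normal(7, 5, n))), 61, 90),
            np.clip(np.round(rng.normal(52, 5, n)), 40, 60),
        ).astype(int)
        if group in ("control", "lc_only"):
            copd_dx = np.zeros(n, dtype=bool)
        elif group in ("copd", "lc_copd"):
            copd_dx = np.ones(n, dtype=bool)
        else:  # spirometry missing: published whole-cohort prevalence
            copd_dx = rng.random(n) < clin["prior_copd_dx"]
        pct, ratio = _sample_spirometry(rng, group, n)
        df = pd.DataFrame(
            {
                "subject_id": [
                    f"SIM-{_GROUP_PREFIX[group]}{i:06d}" for i in range(n)
                ],
                "disease_label": _GROUP_LABEL[group],
                "age": age,
                "sex": np.where(rng.random(n) < clin["male"], "M", "F"),
                "fev1_pct_pred": pct,
                "fev1_fvc": ratio,
                "pack_years": np.round(np.clip(rng.normal(42, 20, n), 20, 150), 1),
                "family_history_lc": rng.random(n) < clin["fhx_lc"],
                "prior_copd_dx": copd_dx,
            }
        )
        gkey = "lc_copd" if group == "lc_nospiro" else group
        done: set[str] = set()
        for entry in panel:
            snp = entry.snp_id
            if snp in done or snp not in spec.genotype_probs:
                continue
            probs = np.asarray(spec.genotype_probs[snp][gkey], dtype=float)
            if snp in paired and paired[snp][0] in spec.genotype_probs:
                other, target, is_first = paired[snp]
                if not is_first:
                    continue  # drawn together with its partner
                q = np.asarray(spec.genotype_probs[other][gkey], dtype=float)
                joint = _joint_genotype_probs(probs, q, target)
                flat = rng.choice(9, size=n, p=joint.ravel() / joint.sum())
                gi, gj = np.divmod(flat, 3)
                df[snp] = np.asarray(entry.alphabet, dtype=object)[gi]
                df[other] = np.asarray(by_id[other].alphabet, dtype=object)[gj]
                done.update((snp, other))
            else:
                idx = rng.choice(3, size=n, p=probs)
                df[snp] = np.asarray(entry.alphabet, dtype=object)[idx]
                done.add(snp)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def genotype_concordance(
    cohort: pd.DataFrame, snp_a: str, snp_b: str
) -> float:
    """Realised genotype-class agreement between two SNP columns.

    Genotype classes correspond positionally (major-hom with major-hom and
    so on); rows with a missing call at either SNP are dropped.
    """
    a, b = cohort[snp_a], cohort[snp_b]
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        raise ValueError("no jointly called subjects")
    # compare by position in each SNP's alphabet
    panel = {e.snp_id: e for e in default_panel()}
    if snp_a in panel and snp_b in panel:
        pos_a = a[ok].map({g: i for i, g in enumerate(panel[snp_a].alphabet)})
        pos_b = b[ok].map({g: i for i, g in enumerate(panel[snp_b].alphabet)})
        return float((pos_a == pos_b).mean())
    return float((a[ok] == b[ok]).mean())


def spec_from_battery(
    battery_results, group_sizes: Mapping[str, int] | None = None, seed: int = 0
) -> GeneratorSpec:
    """Plug-in generator spec from fitted battery genotype counts.

    The spec's expected per-group genotype counts equal the observed ones
    (frequency plug-in), enabling fixture -> spec -> sample round trips.
    """
    counts = battery_results.genotype_counts
    if not counts:
        raise ValueError("battery results carry no genotype counts")
    gmap = {
        "control": "CONTROL",
        "copd": "COPD",
        "lc_copd": "LC_WITH_COPD",
        "lc_only": "LC_ONLY",
    }
    panel = {e.snp_id: e for e in battery_results.model.panel}
    probs: dict[str, dict[str, tuple]] = {}
    sizes: dict[str, int] = {}
    for snp, per_group in counts.items():
        entry = panel[snp]
        probs[snp] = {}
        for g, src in gmap.items():
            triple = np.array(
                [per_group[src][geno] for geno in entry.alphabet], dtype=float
            )
            total = triple.sum()
            if total == 0:
                raise ValueError(f"{snp}: no calls in group {src}")
            probs[snp][g] = tuple(triple / total)
            sizes.setdefault(g, int(total))
            sizes[g] = max(sizes[g], int(total))
    if group_sizes is not None:
        sizes = dict(group_sizes)
    return GeneratorSpec(group_sizes=sizes, genotype_probs=probs, seed=seed)
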
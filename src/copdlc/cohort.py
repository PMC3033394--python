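"""Subject-level cohort model: spirometric COPD classification, analysis-group
assignment, tabular I/O and genotype QC.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per subject and the columns listed in :data:`REQUIRED_COLUMNS` plus one
genotype column per panel rsID. Airflow obstruction is graded from
pre-bronchodilator spirometry: GOLD 2+ means FEV1/FVC < 70% together with
FEV1 <= 80% of predicted; FEV1/FVC < 70% with preserved FEV1 is GOLD 1.
Controls are "resistant" smokers — volunteers with any obstruction (GOLD 1+)
are excluded from analysis.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, SnpPanelEntry

#: required non-genotype columns of a cohort table, in file order
REQUIRED_COLUMNS = (
    "subject_id",
    "disease_label",
    "age",
    "sex",
    "fev1_pct_pred",
    "fev1_fvc",
    "pack_years",
    "family_history_lc",
    "prior_copd_dx",
)

#: per-group genotype call-rate threshold below which a QC flag is raised
CALL_RATE_THRESHOLD = 0.95


class SpirometryError(ValueError):
    """Spirometry unusable for COPD classification."""


class PhenotypeError(ValueError):
    """Disease label inconsistent with spirometry."""


class CohortValidationError(ValueError):
    """Cohort table failed validation; ``.row_errors`` lists the offenders."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


class DiseaseLabel(str, enum.Enum):
    CONTROL_VOLUNTEER = "CONTROL_VOLUNTEER"
    COPD_CASE = "COPD_CASE"
    LUNG_CANCER_CASE = "LUNG_CANCER_CASE"


class CopdClass(str, enum.Enum):
    NONE = "NONE"
    GOLD1 = "GOLD1"
    GOLD2PLUS = "GOLD2PLUS"


class AnalysisGroup(str, enum.Enum):
    CONTROL = "CONTROL"
    COPD = "COPD"
    LC_ALL = "LC_ALL"
    LC_WITH_COPD = "LC_WITH_COPD"
    LC_ONLY = "LC_ONLY"
    EXCLUDED = "EXCLUDED"


@dataclass
class Subject:
    """One study subject (row of the cohort table)."""

    subject_id: str
    disease_label: DiseaseLabel
    age: int
    sex: str
    fev1_pct_pred: float  # percent predicted; NaN if not measured
    fev1_fvc: float  # ratio as percent; NaN if not measured
    pack_years: float
    family_history_lc: bool
    prior_copd_dx: bool
    genotypes: dict[str, str] = field(default_factory=dict)

    @property
    def has_spirometry(self) -> bool:
        a = not (isinstance(self.fev1_pct_pred, float) and math.isnan(self.fev1_pct_pred))
        b = not (isinstance(self.fev1_fvc, float) and math.isnan(self.fev1_fvc))
        if a != b:
            raise SpirometryError(
                f"{self.subject_id}: FEV1%pred and FEV1/FVC must be jointly "
                f"present or jointly missing"
            )
        return a


def classify_gold(fev1_pct_pred: float, fev1_fvc: float) -> CopdClass:
    """Grade airflow obstruction from pre-bronchodilator spirometry.

    GOLD2PLUS iff FEV1/FVC < 70 and FEV1 %predicted <= 80; GOLD1 iff
    FEV1/FVC < 70 with FEV1 %predicted > 80; NONE otherwise. Thresholds are
    applied exactly as stated: a ratio of precisely 70 is non-obstructed.
    """
    for name, v in (("fev1_pct_pred", fev1_pct_pred), ("fev1_fvc", fev1_fvc)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise SpirometryError(f"{name} is missing")
        if not math.isfinite(v) or v < 0:
            raise SpirometryError(f"{name}={v!r} is not a usable measurement")
    if fev1_fvc < 70:
        return CopdClass.GOLD2PLUS if fev1_pct_pred <= 80 else CopdClass.GOLD1
    return CopdClass.NONE


def assign_analysis_group(subject: Subject) -> AnalysisGroup:
    """Map a subject to its primary analysis group.

    Control volunteers with any airflow obstruction (GOLD 1+) are EXCLUDED.
    COPD cases must meet GOLD 2+ (else :class:`PhenotypeError`). Lung-cancer
    cases belong to LC_ALL; those with usable spirometry additionally fall in
    LC_WITH_COPD (GOLD 2+) or LC_ONLY, while cases without spirometry count
    toward LC_ALL contrasts only.
    """
    label = DiseaseLabel(subject.disease_label)
    if label is DiseaseLabel.LUNG_CANCER_CASE:
        if not subject.has_spirometry:
            return AnalysisGroup.LC_ALL
        gold = classify_gold(subject.fev1_pct_pred, subject.fev1_fvc)
        return (
            AnalysisGroup.LC_WITH_COPD
            if gold is CopdClass.GOLD2PLUS
            else AnalysisGroup.LC_ONLY
        )
    gold = classify_gold(subject.fev1_pct_pred, subject.fev1_fvc)
    if label is DiseaseLabel.CONTROL_VOLUNTEER:
        return (
            AnalysisGroup.CONTROL if gold is CopdClass.NONE else AnalysisGroup.EXCLUDED
        )
    # COPD case
    if gold is not CopdClass.GOLD2PLUS:
        raise PhenotypeError(
            f"{subject.subject_id}: COPD case does not meet GOLD 2+ criteria "
            f"(FEV1%pred={subject.fev1_pct_pred}, FEV1/FVC={subject.fev1_fvc})"
        )
    return AnalysisGroup.COPD


def assign_groups(cohort: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`assign_analysis_group` over a cohort table.

    Returns a string Series (values of :class:`AnalysisGroup`). Lung-cancer
    rows get their sub-phenotype label (LC_WITH_COPD / LC_ONLY) or ``LC_ALL``
    when spirometry is absent; membership of the pooled LC_ALL group is
    recovered with :func:`group_mask`.
    """
    label = cohort["disease_label"].astype(str)
    pct = pd.to_numeric(cohort["fev1_pct_pred"], errors="coerce")
    ratio = pd.to_numeric(cohort["fev1_fvc"], errors="coerce")
    has_spiro = pct.notna() & ratio.notna()
    if (pct.notna() != ratio.notna()).any():
        bad = cohort.loc[pct.notna() != ratio.notna(), "subject_id"].tolist()
        raise SpirometryError(
            f"half-missing spirometry for subjects {bad[:5]}"
        )
    gold2 = has_spiro & (ratio < 70) & (pct <= 80)
    gold1 = has_spiro & (ratio < 70) & (pct > 80)

    out = pd.Series(AnalysisGroup.EXCLUDED.value, index=cohort.index, dtype=object)
    is_ctrl = label == DiseaseLabel.CONTROL_VOLUNTEER.value
    is_copd = label == DiseaseLabel.COPD_CASE.value
    is_lc = label == DiseaseLabel.LUNG_CANCER_CASE.value
    unknown = ~(is_ctrl | is_copd | is_lc)
    if unknown.any():
        raise CohortValidationError(
            f"unknown disease labels: {sorted(label[unknown].unique())}"
        )
    if ((is_ctrl | is_copd) & ~has_spiro).any():
        bad = cohort.loc[(is_ctrl | is_copd) & ~has_spiro, "subject_id"].tolist()
        raise SpirometryError(f"missing spirometry for non-LC subjects {bad[:5]}")
    out[is_ctrl & ~(gold1 | gold2)] = AnalysisGroup.CONTROL.value
    if (is_copd & ~gold2).any():
        bad = cohort.loc[is_copd & ~gold2, "subject_id"].tolist()
        raise PhenotypeError(f"COPD cases failing GOLD 2+ criteria: {bad[:5]}")
    out[is_copd] = AnalysisGroup.COPD.value
    out[is_lc & ~has_spiro] = AnalysisGroup.LC_ALL.value
    out[is_lc & gold2] = AnalysisGroup.LC_WITH_COPD.value
    out[is_lc & has_spiro & ~gold2] = AnalysisGroup.LC_ONLY.value
    return out


def group_mask(groups: pd.Series, group: AnalysisGroup | str) -> pd.Series:
    """Boolean membership mask, resolving the overlapping group definitions.

    ``LC_ALL`` covers every lung-cancer case (both sub-phenotypes plus cases
    lacking spirometry); the other groups are literal matches.
    """
    group = AnalysisGroup(group)
    if group is AnalysisGroup.LC_ALL:
        return groups.isin(
            [
                AnalysisGroup.LC_ALL.value,
                AnalysisGroup.LC_WITH_COPD.value,
                AnalysisGroup.LC_ONLY.value,
            ]
        )
    return groups == group.value


def _coerce_bool(value: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"{where}: cannot parse boolean {value!r}")


def read_cohort_table(
    path: str | Path, panel: Sequence[SnpPanelEntry]
) -> pd.DataFrame:
    """Read and validate a tab-separated cohort table.

    One row per subject; missing genotypes encoded ``"NN"``, missing
    spirometry as empty fields. All rows are validated (genotypes against
    each SNP's alphabet, numerics, booleans) and every offending row is
    collected into the raised :class:`CohortValidationError`.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        comment="#",
        keep_default_na=False,
    )
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"{path}: missing columns {missing_cols}")
    by_id = {e.snp_id: e for e in panel}
    snp_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    unknown = [c for c in snp_cols if c not in by_id]
    if unknown:
        raise CohortValidationError(f"{path}: unknown SNP columns {unknown}")

    errors: list[tuple[int, str]] = []
    out = pd.DataFrame(index=df.index)
    out["subject_id"] = df["subject_id"]
    out["disease_label"] = df["disease_label"]
    bad_label = ~df["disease_label"].isin([d.value for d in DiseaseLabel])
    for i in df.index[bad_label]:
        errors.append((i, f"bad disease_label {df.at[i, 'disease_label']!r}"))
    for col, kind in (
        ("age", "int"),
        ("fev1_pct_pred", "optfloat"),
        ("fev1_fvc", "optfloat"),
        ("pack_years", "float"),
    ):
        raw = df[col].replace("", np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() if kind == "optfloat" else vals.isna()
        for i in df.index[bad]:
            errors.append((i, f"malformed numeric field {col}={df.at[i, col]!r}"))
        out[col] = vals.round().astype("Int64") if kind == "int" else vals.astype(float)
    out["sex"] = df["sex"]
    for i in df.index[~df["sex"].isin(["M", "F"])]:
        errors.append((i, f"bad sex {df.at[i, 'sex']!r}"))
    for col in ("family_history_lc", "prior_copd_dx"):
        parsed = []
        for i, v in df[col].items():
            try:
                parsed.append(_coerce_bool(v, col))
            except ValueError as exc:
                errors.append((i, str(exc)))
                parsed.append(False)
        out[col] = parsed
    for col in snp_cols:
        entry = by_id[col]
        ok = df[col].isin(list(entry.alphabet) + [MISSING])
        for i in df.index[~ok]:
            errors.append(
                (i, f"genotype {df.at[i, col]!r} outside {col} alphabet "
                    f"{entry.alphabet}")
            )
        out[col] = df[col]
    if errors:
        raise CohortValidationError(
            f"{path}: {len(errors)} row-level errors (first: row "
            f"{errors[0][0]}: {errors[0][1]})",
            row_errors=errors,
        )
    return out[[*REQUIRED_COLUMNS, *snp_cols]]


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table in the TSV dialect read by :func:`read_cohort_table`."""
    df = cohort.copy()
    for col in ("family_history_lc", "prior_copd_dx"):
        df[col] = df[col].map({True: "1", False: "0"})
    snp_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    df = df[list(REQUIRED_COLUMNS) + snp_cols]
    for col in ("fev1_pct_pred", "fev1_fvc"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{float(v):g}")
    df["pack_years"] = df["pack_years"].map(lambda v: f"{float(v):g}")
    df.to_csv(path, sep="\t", index=False)


def subjects_from_frame(cohort: pd.DataFrame) -> Iterable[Subject]:
    """Iterate a cohort table as :class:`Subject` records."""
    snp_cols = [c for c in cohort.columns if c not in REQUIRED_COLUMNS]
    for _, row in cohort.iterrows():
        yield Subject(
            subject_id=row["subject_id"],
            disease_label=DiseaseLabel(row["disease_label"]),
            age=int(row["age"]),
            sex=row["sex"],
            fev1_pct_pred=float(row["fev1_pct_pred"])
            if pd.notna(row["fev1_pct_pred"])
            else float("nan"),
            fev1_fvc=float(row["fev1_fvc"])
            if pd.notna(row["fev1_fvc"])
            else float("nan"),
            pack_years=float(row["pack_years"]),
            family_history_lc=bool(row["family_history_lc"]),
            prior_copd_dx=bool(row["prior_copd_dx"]),
            genotypes={c: row[c] for c in snp_cols},
        )


def snp_call_rate(
    cohort: pd.DataFrame, snp_id: str, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Per-group genotype call rate for one SNP.

    Returns a frame with columns ``group, n, n_called, call_rate, flagged``;
    ``flagged`` is True where the rate falls below
    :data:`CALL_RATE_THRESHOLD`. With ``groups=None`` the whole cohort is a
    single group labelled ``ALL``.
    """
    if snp_id not in cohort.columns:
        raise KeyError(f"unknown SNP {snp_id!r}")
    if len(cohort) == 0:
        raise CohortValidationError("empty cohort")
    if groups is None:
        groups = pd.Series("ALL", index=cohort.index)
    called = cohort[snp_id] != MISSING
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        n = len(idx)
        nc = int(called.loc[idx].sum())
        rate = nc / n
        rows.append(
            {
                "group": g,
                "n": n,
                "n_called": nc,
                "call_rate": rate,
                "flagged": rate < CALL_RATE_THRESHOLD,
            }
        )
    return pd.DataFrame(rows)
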
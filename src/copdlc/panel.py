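"""SNP panel definitions.

A panel entry describes one biallelic SNP: its genotype alphabet (ordered
major-homozygote, heterozygote, minor-homozygote as tabulated), the genotype
class treated as "exposed" in the 2x2 collapse, and — for SNPs that enter the
composite susceptibility score — a direction: +1 if carrying the risk
genotype confers susceptibility, -1 if it is protective. Entries with
direction 0 are typed and tested for association but do not contribute to
the score.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

MISSING = "NN"

EFFECT_CLASSES = ("G0", "G1", "G2", "G3", "UNASSIGNED")


class PanelError(ValueError):
    """Malformed panel definition."""


@dataclass(frozen=True)
class SnpPanelEntry:
    """One SNP of the genotyping panel.

    Parameters
    ----------
    snp_id : str
        rsID; also the genotype column name in cohort tables.
    gene, locus : str
        Candidate gene symbol and chromosome-band label.
    alphabet : tuple of str
        The three genotype strings, in tabulation order.
    risk_genotypes : frozenset of str
        Nonempty strict subset of ``alphabet`` counted as "exposed".
    direction : int
        +1 susceptible, -1 protective, 0 not in the composite score.
    effect_class : str
        Published G0-G3 class, or ``"UNASSIGNED"``.
    risk_allele : str
        Single-letter allele used as exposure in the allelic model.
    """

    snp_id: str
    gene: str
    locus: str
    alphabet: tuple[str, ...]
    risk_genotypes: frozenset[str]
    direction: int
    effect_class: str = "UNASSIGNED"
    risk_allele: str = ""

    def __post_init__(self) -> None:
        if len(self.alphabet) != 3:
            raise PanelError(f"{self.snp_id}: alphabet must have 3 genotypes")
        if not self.risk_genotypes:
            raise PanelError(f"{self.snp_id}: empty risk genotype set")
        if not self.risk_genotypes < set(self.alphabet):
            raise PanelError(
                f"{self.snp_id}: risk genotypes must be a strict subset of "
                f"the alphabet"
            )
        if self.direction not in (-1, 0, 1):
            raise PanelError(f"{self.snp_id}: direction must be -1, 0 or +1")
        if self.effect_class not in EFFECT_CLASSES:
            raise PanelError(f"{self.snp_id}: bad effect class {self.effect_class}")

    @property
    def in_score(self) -> bool:
        """Whether this SNP contributes to the composite score."""
        return self.direction != 0

    @property
    def alleles(self) -> tuple[str, str]:
        """The two alleles, inferred from the homozygote genotypes."""
        return self.alphabet[0][0], self.alphabet[2][0]


def _entry_from_mapping(raw: dict) -> SnpPanelEntry:
    try:
        return SnpPanelEntry(
            snp_id=str(raw["snp_id"]),
            gene=str(raw.get("gene", "")),
            locus=str(raw.get("locus", "")),
            alphabet=tuple(str(g) for g in raw["alphabet"]),
            risk_genotypes=frozenset(str(g) for g in raw["risk_genotypes"]),
            direction=int(raw.get("direction", 0)),
            effect_class=str(raw.get("effect_class", "UNASSIGNED")),
            risk_allele=str(raw.get("risk_allele", "")),
        )
    except KeyError as exc:  # pragma: no cover - message only
        raise PanelError(f"panel entry missing required key {exc}") from exc


def load_panel(path: str | Path) -> list[SnpPanelEntry]:
    """Read a panel definition from a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "panel" not in doc:
        raise PanelError(f"{path}: expected a top-level 'panel' list")
    entries = [_entry_from_mapping(raw) for raw in doc["panel"]]
    ids = [e.snp_id for e in entries]
    if len(set(ids)) != len(ids):
        raise PanelError("duplicate snp_id in panel")
    return entries


def default_panel() -> list[SnpPanelEntry]:
    """The packaged 12-SNP GWAS candidate panel (9 of them scored)."""
    ref = resources.files("copdlc").joinpath("data/panel_gwas12.yaml")
    with resources.as_file(ref) as path:
        return load_panel(path)


def score_panel(panel: Sequence[SnpPanelEntry]) -> list[SnpPanelEntry]:
    """The subset of a panel that enters the composite score."""
    return [e for e in panel if e.in_score]
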
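"""Tiered gene-panel construction.

Phase I is a bespoke per-patient panel: the union of genes mapped from
the patient's HPO phenotype terms with gene lists supplied by the
referring clinical team. Phase II is a broad disease-gene scope (a
developmental-disorder gene list united with an OMIM-morbid-like list).
Phase III opens the analysis genome-wide and is represented by a
universal-scope sentinel whose membership test always passes, including
for variants in no annotated gene.

Gene identity is by symbol with case-insensitive deduplication; alias
resolution is out of scope. The HPO→gene map is a supplied two-column
table (term, gene) standing in for interactive panel resources, keeping
panel construction reproducible offline. By default a term contributes
only its own mapped genes (no ontology propagation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

HPO_TERM_RE = re.compile(r"^HP:\d{7}$")

VALID_MOI = {"recessive", "dominant", "x_linked", "unknown"}


class PanelError(ValueError):
    """Raised when a panel cannot be built (empty result, missing file)."""


@dataclass(frozen=True)
class PhenotypeProfile:
    """A patient's clinical features encoded as HPO terms."""

    patient_id: str
    hpo_terms: frozenset[str]

    def __post_init__(self) -> None:
        bad = [t for t in self.hpo_terms if not HPO_TERM_RE.match(t)]
        if bad:
            raise PanelError(f"malformed HPO term(s): {sorted(bad)}")


@dataclass
class GenePanel:
    """A named gene scope with per-gene provenance and optional MOI map.

    Symbols are stored upper-cased; ``universal=True`` marks the
    genome-wide phase III sentinel, whose membership test always passes.
    """

    name: str
    genes: set[str] = field(default_factory=set)
    moi_by_gene: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)
    universal: bool = False

    def __post_init__(self) -> None:
        if not self.universal:
            if not self.genes:
                raise PanelError(f"empty panel: {self.name!r}")
            missing = {g for g in self.genes if not self.provenance.get(g)}
            if missing:
                raise PanelError(
                    f"panel {self.name!r}: genes without provenance: {sorted(missing)}"
                )

    def __contains__(self, gene: str) -> bool:
        if self.universal:
            return True
        return gene.upper() in self.genes

    def moi(self, gene: str) -> str:
        return self.moi_by_gene.get(gene.upper(), "unknown")


def _union(
    name: str,
    sources: Iterable[tuple[str, Iterable[str]]],
    moi_by_gene: Optional[Mapping[str, str]] = None,
) -> GenePanel:
    genes: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for source_label, source_genes in sources:
        for g in source_genes:
            sym = g.strip().upper()
            if not sym:
                continue
            genes.add(sym)
            provenance.setdefault(sym, [])
            if source_label not in provenance[sym]:
                provenance[sym].append(source_label)
    moi = {
        g.upper(): m
        for g, m in (moi_by_gene or {}).items()
        if g.upper() in genes
    }
    return GenePanel(name=name, genes=genes, moi_by_gene=moi, provenance=provenance)


def build_phase1_panel(
    profile: PhenotypeProfile,
    hpo_gene_map: Mapping[str, Iterable[str]],
    clinician_genes: Iterable[str] = (),
    moi_by_gene: Optional[Mapping[str, str]] = None,
) -> GenePanel:
    """Bespoke patient panel: HPO-mapped genes ∪ clinician gene lists.

    Unknown HPO terms contribute nothing (the map simply lacks them);
    an empty union is an error — phase I cannot run without a scope.
    """
    sources: list[tuple[str, Iterable[str]]] = []
    for term in sorted(profile.hpo_terms):
        mapped = hpo_gene_map.get(term, ())
        sources.append((term, mapped))
    sources.append(("clinician list", list(clinician_genes)))
    try:
        return _union(
            f"phase I bespoke ({profile.patient_id})", sources, moi_by_gene
        )
    except PanelError:
        raise PanelError(
            f"empty phase I panel for {profile.patient_id}: no HPO term mapped "
            "to a gene and no clinician genes supplied"
        ) from None


def build_phase2_panel(
    ddg2p_genes: Iterable[str],
    omim_morbid_genes: Iterable[str],
    moi_by_gene: Optional[Mapping[str, str]] = None,
) -> GenePanel:
    """Broad disease-gene scope: developmental-disorder ∪ OMIM-morbid genes."""
    try:
        return _union(
            "phase II broad",
            [("DDG2P", list(ddg2p_genes)), ("OMIM morbid", list(omim_morbid_genes))],
            moi_by_gene,
        )
    except PanelError:
        raise PanelError("empty phase II panel: both gene lists are empty") from None


def phase3_scope() -> GenePanel:
    """Genome-wide sentinel: every gene (and no-gene) is in scope."""
    panel = GenePanel(name="phase III genome-wide", universal=True)
    return panel


# ---------------------------------------------------------------------------
# file readers (one term/gene per line; 2-column TSV for the HPO map)


def read_hpo_terms(path: str | Path) -> frozenset[str]:
    lines = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(lines)


def read_hpo_gene_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV mapping HPO term → gene symbol (one pair per row)."""
    mapping: dict[str, set[str]] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise PanelError(f"{path}: line {n}: expected 'term<TAB>gene'")
        term, gene = parts[0].strip(), parts[1].strip()
        mapping.setdefault(term, set()).add(gene.upper())
    return mapping


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; optional second TSV column is ignored."""
    p = Path(path)
    if not p.exists():
        raise PanelError(f"gene list file not found: {p}")
    out = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t")[0].strip())
    return out


def read_gene_moi(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene symbol → mode of inheritance."""
    p = Path(path)
    if not p.exists():
        raise PanelError(f"gene MOI file not found: {p}")
    moi: dict[str, str] = {}
    for n, line in enumerate(p.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or parts[1].strip() not in VALID_MOI:
            raise PanelError(
                f"{p}: line {n}: expected 'gene<TAB>moi' with moi in {sorted(VALID_MOI)}"
            )
        moi[parts[0].strip().upper()] = parts[1].strip()
    return moi
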
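"""Per-gene configuration: validity tiers, domains, hotspots, thresholds.

Everything gene-specific that the criteria engine reads lives here as
*data*, loaded from a YAML/JSON document, never hard-coded in evaluator
logic.  The shipped default knowledge base covers the 16 supported genes;
its PM1 domain coordinates and PM5_Strong hotspot residues are curated,
replaceable defaults (marked ``provisional`` in the file) — a deploying
laboratory is expected to substitute its own curated coordinates.

The module also owns the two operations that *build* knowledge-base
content: mutational-hotspot detection from case-count tables, and
analogous-residue mapping through gene-family alignments.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import AlignIO
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .evidence_model import SUPPORTED_GENES, MechanismRoute


class ValidityTier(str, enum.Enum):
    Definitive = "Definitive"
    Strong = "Strong"
    Moderate = "Moderate"
    Limited = "Limited"


class ParalogFamily(str, enum.Enum):
    RAF = "RAF"
    RAS = "RAS"
    MAP2K = "MAP2K"
    SOS = "SOS"
    none = "none"


class DomainInterval(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    start: int = Field(ge=1)
    end: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self):
        if self.end < self.start:
            raise ValueError(f"domain {self.name}: end < start")
        return self


class AssayDescriptor(BaseModel):
    """An approved functional assay and, for dual-mechanism genes, which
    disease mechanism an abnormal result supports."""

    model_config = ConfigDict(extra="forbid")
    assay_id: str
    description: str = ""
    mechanism_if_abnormal: Optional[MechanismRoute] = None


PP2_GENES = frozenset({"BRAF", "MAP2K1", "PTPN11", "PPP1CB"})


class GeneProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gene: str
    validity_tier: ValidityTier
    inheritance_modes: set[str] = Field(default_factory=lambda: {"AD"})
    pp2_applicable: bool = False
    pm1_domains: list[DomainInterval] = Field(default_factory=list)
    pm5_strong_hotspots: list[int] = Field(default_factory=list)
    pvs1_applicable: bool = False
    pm3_applicable: bool = False
    ba1_threshold: float = 0.0005
    bs1_threshold: float = 0.00025
    pm2_threshold: float = 0.000025
    approved_assays: list[AssayDescriptor] = Field(default_factory=list)
    paralog_family: ParalogFamily = ParalogFamily.none

    @model_validator(mode="after")
    def _gene_specific_rules(self):
        if self.gene not in SUPPORTED_GENES:
            raise ValueError(f"unsupported gene {self.gene!r}")
        if (self.pvs1_applicable or self.pm3_applicable) and self.gene != "LZTR1":
            raise ValueError(
                f"{self.gene}: PVS1/PM3 are applicable only to LZTR1"
            )
        if self.pp2_applicable and self.gene not in PP2_GENES:
            raise ValueError(
                f"{self.gene}: PP2 is restricted to genes with gnomAD missense "
                "z-score >= 3.09 (BRAF, MAP2K1, PTPN11, PPP1CB)"
            )
        if self.gene == "PPP1CB" and self.approved_assays:
            raise ValueError("PPP1CB has no approved functional assays")
        ordered = sorted(self.pm1_domains, key=lambda d: d.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.gene}: domains {a.name} and {b.name} overlap"
                )
        return self


# --------------------------------------------------------------------------
# Case-count tables and hotspot detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseCountRow:
    """One observed variant at a residue with its proband tally.

    ``alt_change`` is the alternate amino acid for missense rows or a splice
    flag (e.g. ``"splice"``) — hotspot detection only needs distinctness.
    """

    gene: str
    residue_position: int
    alt_change: str
    classification: str  # P, LP, B, LB, VUS
    proband_count: int
    benign_variation_present: bool = False


@dataclass
class CaseCountTable:
    rows: list[CaseCountRow] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CaseCountTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        rows = []
        for _, r in df.iterrows():
            rows.append(
                CaseCountRow(
                    gene=r["gene"],
                    residue_position=int(r["residue_position"]),
                    alt_change=r["alt_change"],
                    classification=r["classification"],
                    proband_count=int(r["proband_count"]),
                    benign_variation_present=str(
                        r.get("benign_variation_present", "false")
                    ).strip().lower()
                    in {"1", "true", "yes"},
                )
            )
        return cls(rows)


def detect_pm5_strong_hotspots(table: CaseCountTable) -> list[tuple[str, int]]:
    """Detect residues qualifying for strength-elevated PM5.

    A residue is a hotspot iff, at that (gene, position):

    * at least 2 *distinct* P/LP alternate changes are recorded,
    * the summed proband count over those P/LP changes is at least 5, and
    * no benign variation is flagged at the residue.

    The change type is deliberately ignored beyond distinctness — its impact
    is assessed per-variant via the in-silico criteria.
    """
    by_residue: dict[tuple[str, int], list[CaseCountRow]] = {}
    for row in table.rows:
        by_residue.setdefault((row.gene, row.residue_position), []).append(row)

    hotspots = []
    for key in sorted(by_residue):
        rows = by_residue[key]
        plp = [r for r in rows if r.classification in ("P", "LP")]
        distinct_changes = {r.alt_change for r in plp}
        total_probands = sum(r.proband_count for r in plp)
        benign = any(r.benign_variation_present for r in rows)
        if len(distinct_changes) >= 2 and total_probands >= 5 and not benign:
            hotspots.append(key)
    return hotspots


# --------------------------------------------------------------------------
# Paralog alignments
# --------------------------------------------------------------------------

class ParalogAlignment:
    """A gene-family protein alignment with residue <-> column maps.

    Built once from an aligned FASTA (one record per gene, id = gene
    symbol); the per-gene map is bijective over non-gap positions.
    Coordinates are 1-based inclusive protein residues (HGVS p. convention).
    """

    def __init__(self, family: ParalogFamily, sequences: dict[str, str]):
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences have unequal lengths")
        self.family = family
        self.sequences = dict(sequences)
        self._pos_to_col: dict[str, dict[int, int]] = {}
        self._col_to_pos: dict[str, dict[int, int]] = {}
        for gene, seq in sequences.items():
            p2c, c2p = {}, {}
            pos = 0
            for col, ch in enumerate(seq):
                if ch != "-":
                    pos += 1
                    p2c[pos] = col
                    c2p[col] = pos
            self._pos_to_col[gene] = p2c
            self._col_to_pos[gene] = c2p

    @classmethod
    def from_fasta(cls, family: ParalogFamily, path: str | Path) -> "ParalogAlignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls(family, {rec.id: str(rec.seq) for rec in aln})

    @property
    def genes(self) -> list[str]:
        return sorted(self.sequences)

    def column_of(self, gene: str, position: int) -> int:
        if gene not in self.sequences:
            raise KeyError(f"{gene} is not in the {self.family.value} family alignment")
        try:
            return self._pos_to_col[gene][position]
        except KeyError:
            raise ValueError(
                f"{gene} residue {position} out of range for the alignment"
            ) from None

    def residue_at(self, gene: str, column: int) -> Optional[int]:
        return self._col_to_pos.get(gene, {}).get(column)


def map_analogous_residue(
    family_alignment: ParalogAlignment,
    source_gene: str,
    source_position: int,
    include_source: bool = False,
) -> list[tuple[str, int]]:
    """Map a residue to the analogous residue of every other family member.

    Family members with a gap in the source residue's alignment column
    contribute no entry.  With ``include_source`` the (identity) mapping of
    the source gene itself is included too.
    """
    col = family_alignment.column_of(source_gene, source_position)
    out = []
    for gene in family_alignment.genes:
        if gene == source_gene and not include_source:
            continue
        pos = family_alignment.residue_at(gene, col)
        if pos is not None:
            out.append((gene, pos))
    return out


def in_pm1_domain(profile: GeneProfile, position: int) -> Optional[str]:
    """Name of the well-established functional domain containing ``position``.

    Genes with no defined PM1 domains (SOS1/SOS2, LZTR1, PPP1CB) always
    return ``None``; boundaries are 1-based inclusive.
    """
    for dom in profile.pm1_domains:
        if dom.start <= position <= dom.end:
            return dom.name
    return None


# --------------------------------------------------------------------------
# Known-variant index (for PS1 and baseline PM5)
# --------------------------------------------------------------------------

@dataclass
class KnownVariantIndex:
    """Previously classified variants, keyed for PS1/PM5 lookups.

    ``missense``: (gene, residue, alt_aa) -> classification.
    ``splice``: (gene, hgvs_c location) -> (classification, predicted impact
    label as produced by the agreed in-silico tools).
    """

    missense: dict[tuple[str, int, str], str] = field(default_factory=dict)
    splice: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownVariantIndex":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        idx = cls()
        for _, r in df.iterrows():
            if r.get("residue_position", "") not in ("", "."):
                idx.missense[
                    (r["gene"], int(r["residue_position"]), r["alt_aa"])
                ] = r["classification"]
            else:
                idx.splice[(r["gene"], r["hgvs_c"])] = (
                    r["classification"],
                    r.get("predicted_impact", ""),
                )
        return idx

    def pathogenic_missense_at(
        self, gene: str, position: int, min_class: str = "P"
    ) -> list[tuple[str, str]]:
        """All (alt_aa, classification) P/LP entries at a residue."""
        accepted = ("P",) if min_class == "P" else ("P", "LP")
        return [
            (aa, clf)
            for (g, pos, aa), clf in self.missense.items()
            if g == gene and pos == position and clf in accepted
        ]


# --------------------------------------------------------------------------
# Knowledge-base container and loading
# --------------------------------------------------------------------------

class KnowledgeBaseError(ValueError):
    pass


class KnowledgeBase:
    def __init__(
        self,
        profiles: dict[str, GeneProfile],
        alignments: Optional[dict[ParalogFamily, ParalogAlignment]] = None,
    ):
        self.profiles = dict(profiles)
        self.alignments = dict(alignments or {})

    def __contains__(self, gene: str) -> bool:
        return gene in self.profiles

    def __getitem__(self, gene: str) -> GeneProfile:
        try:
            return self.profiles[gene]
        except KeyError:
            raise KnowledgeBaseError(
                f"gene {gene!r} is absent from the knowledge base"
            ) from None

    def alignment_for(self, gene: str) -> Optional[ParalogAlignment]:
        fam = self[gene].paralog_family
        if fam is ParalogFamily.none:
            return None
        return self.alignments.get(fam)

    def hotspot_index(self) -> dict[str, set[int]]:
        return {g: set(p.pm5_strong_hotspots) for g, p in self.profiles.items()}

    def require(self, genes: Iterable[str]) -> None:
        """Fail loudly when any referenced gene is missing."""
        missing = sorted(set(genes) - set(self.profiles))
        if missing:
            raise KnowledgeBaseError(
                f"knowledge base lacks profiles for: {', '.join(missing)}"
            )


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load a YAML or JSON knowledge-base document.

    Alignment paths in the document are resolved relative to the document's
    own directory.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _build_kb(doc, path.parent)


def _build_kb(doc: dict, base_dir: Path) -> KnowledgeBase:
    profiles = {}
    for entry in doc["genes"]:
        entry = dict(entry)
        entry.pop("provisional", None)  # curation flag, not an engine field
        profile = GeneProfile(**entry)
        profiles[profile.gene] = profile
    alignments = {}
    for fam_name, rel in (doc.get("alignments") or {}).items():
        fam = ParalogFamily(fam_name)
        alignments[fam] = ParalogAlignment.from_fasta(fam, base_dir / rel)
    return KnowledgeBase(profiles, alignments)


def default_knowledge_base() -> KnowledgeBase:
    """The knowledge base shipped with the package (provisional defaults)."""
    data = resources.files("rasclass").joinpath("data")
    with resources.as_file(data.joinpath("knowledge_base.yaml")) as p:
        return load_knowledge_base(p)
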
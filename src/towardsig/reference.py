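"""Hierarchical IGHV germline reference: alleles -> genes -> subgroups -> clans.

The reference is an IMGT-gapped FASTA (one record per allele, '.' gaps) plus
a TSV metadata table (allele, gene, subgroup, functionality, orphon,
partial_5prime).  The clan is never read from the metadata: it is a
deterministic function of the subgroup (I: 1/5/7, II: 2/4/6, III: 3).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CLAN_BY_SUBGROUP = {1: "I", 5: "I", 7: "I", 2: "II", 4: "II", 6: "II", 3: "III"}
FUNCTIONALITIES = ("F", "P", "ORF")
_VALID_CHARS = set("ACGT.")
_METADATA_COLUMNS = ["allele", "gene", "subgroup", "functionality", "orphon", "partial_5prime"]
_SUBGROUP_RE = re.compile(r"^IGHV(\d)")


def clan_of(subgroup: int) -> str:
    """Clan of an IGHV subgroup: {1,5,7} -> I, {2,4,6} -> II, {3} -> III."""
    try:
        return CLAN_BY_SUBGROUP[subgroup]
    except KeyError:
        raise ValueError(f"IGHV subgroup must be in 1..7, got {subgroup}") from None


def gene_of(allele_name: str) -> str:
    """Gene name of an allele name, e.g. 'IGHV4-34*02' -> 'IGHV4-34'."""
    return allele_name.split("*", 1)[0]


@dataclass(frozen=True)
class GermlineAllele:
    """One germline IGHV allele with its place in the gene hierarchy.

    ``nt_gapped`` is the IMGT-gapped nucleotide sequence over {A,C,G,T,.};
    positions are 1-based within the gapped frame and '.' never matches a base.
    """

    allele_name: str
    gene_name: str
    subgroup: int
    functionality: str
    orphon: bool
    partial_5prime: bool
    nt_gapped: str
    clan: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "clan", clan_of(self.subgroup))
        m = _SUBGROUP_RE.match(self.allele_name)
        if m and int(m.group(1)) != self.subgroup:
            raise ValueError(
                f"{self.allele_name}: subgroup digit in name ({m.group(1)}) "
                f"disagrees with metadata subgroup {self.subgroup}"
            )
        if self.functionality not in FUNCTIONALITIES:
            raise ValueError(
                f"{self.allele_name}: functionality must be one of {FUNCTIONALITIES}, "
                f"got {self.functionality!r}"
            )
        bad = set(self.nt_gapped) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"{self.allele_name}: sequence contains characters outside ACGT. : {sorted(bad)}"
            )

    def base_at(self, nt_pos: int) -> str:
        """Character at a 1-based gapped position; '.' if beyond sequence end."""
        if nt_pos < 1:
            raise ValueError(f"nt position must be >= 1, got {nt_pos}")
        if nt_pos > len(self.nt_gapped):
            return "."
        return self.nt_gapped[nt_pos - 1]

    @property
    def aa_gapped(self) -> str:
        """Amino-acid translation of the gapped frame; gap codons become '.',
        codons mixing bases and gaps become 'X'."""
        out = []
        for i in range(0, len(self.nt_gapped) - len(self.nt_gapped) % 3, 3):
            codon = self.nt_gapped[i : i + 3]
            if codon == "...":
                out.append(".")
            elif "." in codon:
                out.append("X")
            else:
                out.append(str(Seq(codon).translate()))
        return "".join(out)


@dataclass
class ReferenceDB:
    """Indexed collection of germline alleles keyed by allele name."""

    alleles: dict[str, GermlineAllele]
    gene_index: dict[str, list[str]]
    version_label: str = ""

    def __post_init__(self) -> None:
        indexed = [a for names in self.gene_index.values() for a in names]
        if sorted(indexed) != sorted(self.alleles):
            raise ValueError("gene_index does not partition the allele set")

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, allele_name: str) -> bool:
        return allele_name in self.alleles

    def get(self, allele_name: str) -> GermlineAllele:
        try:
            return self.alleles[allele_name]
        except KeyError:
            raise KeyError(f"allele {allele_name!r} not in reference") from None

    def genes(self) -> list[str]:
        return sorted(self.gene_index)

    def alleles_of(self, gene_name: str) -> list[GermlineAllele]:
        try:
            names = self.gene_index[gene_name]
        except KeyError:
            raise KeyError(f"gene {gene_name!r} not in reference") from None
        return [self.alleles[n] for n in sorted(names)]

    def clan_of_gene(self, gene_name: str) -> str:
        return self.alleles_of(gene_name)[0].clan

    @property
    def frame_length(self) -> int:
        return max((len(a.nt_gapped) for a in self.alleles.values()), default=0)


def _build_index(alleles: dict[str, GermlineAllele]) -> dict[str, list[str]]:
    idx: dict[str, list[str]] = {}
    for name, allele in alleles.items():
        idx.setdefault(allele.gene_name, []).append(name)
    return {g: sorted(ns) for g, ns in idx.items()}


def load_reference(fasta_path: str | Path, metadata_path: str | Path) -> ReferenceDB:
    """Load an IMGT-gapped FASTA plus its TSV metadata into a ReferenceDB.

    Every FASTA record must have a metadata row; sequences with characters
    outside {A,C,G,T,.} (including IUPAC ambiguity codes) are rejected.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata {metadata_path} missing columns: {missing_cols}")
    if meta["allele"].duplicated().any():
        dups = meta.loc[meta["allele"].duplicated(), "allele"].tolist()
        raise ValueError(f"duplicate allele names in metadata: {dups}")
    meta_by_allele = meta.set_index("allele")

    alleles: dict[str, GermlineAllele] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = rec.id
        if name in alleles:
            raise ValueError(f"duplicate allele {name!r} in FASTA")
        if name not in meta_by_allele.index:
            raise ValueError(f"allele {name!r} present in FASTA but absent from metadata")
        row = meta_by_allele.loc[name]
        alleles[name] = GermlineAllele(
            allele_name=name,
            gene_name=str(row["gene"]),
            subgroup=int(row["subgroup"]),
            functionality=str(row["functionality"]),
            orphon=_parse_bool(row["orphon"]),
            partial_5prime=_parse_bool(row["partial_5prime"]),
            nt_gapped=str(rec.seq).upper(),
        )
    return ReferenceDB(alleles=alleles, gene_index=_build_index(alleles),
                       version_label=Path(fasta_path).stem)


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean flag {value!r}")


def filter_reference(
    db: ReferenceDB, drop_orphons: bool = True, drop_partial_5prime: bool = True
) -> ReferenceDB:
    """Return a new ReferenceDB without orphons and/or 5'-partial alleles.

    Genes left with zero alleles are pruned from the gene index; the input
    database is unchanged.  Idempotent.
    """
    kept = {
        name: allele
        for name, allele in db.alleles.items()
        if not (drop_orphons and allele.orphon)
        and not (drop_partial_5prime and allele.partial_5prime)
    }
    if not kept:
        logger.warning("filter_reference removed every allele")
    return ReferenceDB(alleles=kept, gene_index=_build_index(kept),
                       version_label=db.version_label)


def conserved_positions(db: ReferenceDB, gene_name: str) -> set[int]:
    """Gapped positions where all alleles of a gene carry the same base.

    A position counts only if the shared character is a base (not '.').  For
    a single-allele gene this is every non-gap position of that allele.
    Positions past a shorter allele's end are treated as gaps there.
    """
    alleles = db.alleles_of(gene_name)
    length = max(len(a.nt_gapped) for a in alleles)
    out: set[int] = set()
    for pos in range(1, length + 1):
        chars = {a.base_at(pos) for a in alleles}
        if len(chars) == 1 and chars != {"."}:
            out.add(pos)
    return out


def write_reference(db: ReferenceDB, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Re-export a reference as the FASTA + TSV pair consumed by load_reference."""
    names = sorted(db.alleles)
    records = [
        SeqRecord(Seq(db.alleles[n].nt_gapped), id=n, description="") for n in names
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for n in names:
        a = db.alleles[n]
        rows.append(
            {
                "allele": a.allele_name,
                "gene": a.gene_name,
                "subgroup": a.subgroup,
                "functionality": a.functionality,
                "orphon": a.orphon,
                "partial_5prime": a.partial_5prime,
            }
        )
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)
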
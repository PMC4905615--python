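"""Somatic hypermutation features: mutation listing, SH classification, datasets.

A mutation is "shared" (SH) with a germline allele (the Towards Germline,
TowG) when the nucleotide introduced by SHM is present in that germline at
the exact same IMGT-gapped position.  A mutation whose introduced base occurs
in no germline at that position is non-SH.  The scan compares every patient
sequence (sAm) against every reference allele other than its assigned
germline (sBm) and feeds three tabular datasets:

* SHPD    — one row per (mutation, TowG) pair, fully annotated;
* nonSHPD — one row per non-SH mutation;
* GSHD    — one row per (patient sequence, TowG) pair, with SH counts and
            pairwise identities; the input to the towards analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from towardsig.regions import DEFAULT_REGION_SPANS, codon_number, codon_span, region_of, region_span
from towardsig.reference import GermlineAllele, ReferenceDB, conserved_positions, gene_of

if TYPE_CHECKING:  # pragma: no cover
    from towardsig.rearrangements import Rearrangement

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
TRANSITIONS = {frozenset({"A", "G"}), frozenset({"C", "T"})}

#: AID / pol-eta SHM hotspot motifs (IUPAC); matched on the ungapped sBm context.
DEFAULT_HOTSPOT_MOTIFS = ("RGYW", "WRCY", "WA", "TW")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class Mutation:
    """A single nucleotide substitution in IMGT-gapped coordinates."""

    nt_pos: int
    from_base: str
    to_base: str
    region: str | None = None
    is_transition: bool | None = None
    is_replacement: bool | None = None
    in_hotspot: bool | None = None
    codon_number: int = field(init=False)

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError(f"mutation at {self.nt_pos}: from and to base are both {self.from_base}")
        for b in (self.from_base, self.to_base):
            if b not in BASES:
                raise ValueError(f"mutation at {self.nt_pos}: invalid base {b!r}")
        self.codon_number = codon_number(self.nt_pos)

    @property
    def token(self) -> str:
        """Compact text form, e.g. 'a78g' for A->G at gapped position 78."""
        return f"{self.from_base.lower()}{self.nt_pos}{self.to_base.lower()}"


@dataclass(frozen=True)
class SHRecord:
    """One shared mutation together with the germline it moves towards."""

    patient_id: str
    mutation: Mutation
    towg_allele: str


@dataclass(frozen=True)
class AAProperties:
    """IMGT physicochemical classes of one amino acid."""

    hydropathy: str
    volume: str
    chemical: str
    physicochemical: str
    charge: str


_HYDROPATHY = {
    **dict.fromkeys("ACFILMVW", "hydrophobic"),
    **dict.fromkeys("GHPSTY", "neutral"),
    **dict.fromkeys("RNDQEK", "hydrophilic"),
}
_VOLUME = {
    **dict.fromkeys("AGS", "very_small"),
    **dict.fromkeys("NDCPT", "small"),
    **dict.fromkeys("QEHV", "medium"),
    **dict.fromkeys("RILKM", "large"),
    **dict.fromkeys("FWY", "very_large"),
}
_CHEMICAL = {
    **dict.fromkeys("AGILPV", "aliphatic"),
    **dict.fromkeys("FWY", "aromatic"),
    **dict.fromkeys("CM", "sulfur"),
    **dict.fromkeys("ST", "hydroxyl"),
    **dict.fromkeys("RHK", "basic"),
    **dict.fromkeys("DE", "acidic"),
    **dict.fromkeys("NQ", "amide"),
}
_POLARITY = {
    **dict.fromkeys("RNDQEHKSTY", "polar"),
    **dict.fromkeys("ACGILMFPWV", "nonpolar"),
}
_CHARGE = {
    **dict.fromkeys("RHK", "positive"),
    **dict.fromkeys("DE", "negative"),
    **dict.fromkeys("ANCQGILMFPSTWYV", "uncharged"),
}

UNDETERMINED = "undetermined"


def aa_properties(aa: str) -> AAProperties:
    """IMGT-class properties of an amino acid; total over the 20 residues.

    Stop codons ('*') get chemical class 'stop' and every other property
    'undetermined'; anything unrecognized is fully undetermined.
    """
    aa = aa.upper()
    if aa == "*":
        return AAProperties(UNDETERMINED, UNDETERMINED, "stop", UNDETERMINED, UNDETERMINED)
    if aa not in _HYDROPATHY:
        return AAProperties(*([UNDETERMINED] * 5))
    return AAProperties(
        hydropathy=_HYDROPATHY[aa],
        volume=_VOLUME[aa],
        chemical=_CHEMICAL[aa],
        physicochemical=_POLARITY[aa],
        charge=_CHARGE[aa],
    )


# ---------------------------------------------------------------------------
# mutation listing and SH classification


def list_mutations(
    rearr: "Rearrangement",
    db: ReferenceDB,
    region_restriction: str | None = None,
    region_spans: dict[str, tuple[int, int]] | None = None,
) -> list[Mutation]:
    """Nucleotide substitutions between a patient sequence and its sBm germline.

    One Mutation per gapped position where both sequences carry a base
    (never '.' or 'N') and the bases differ; insertions/deletions are out of
    scope.  ``region_restriction`` limits the scan to one V region.
    """
    sbm = db.get(rearr.sbm_allele)
    seq = rearr.nt_gapped.upper()
    if len(seq) != len(sbm.nt_gapped):
        raise ValueError(
            f"{rearr.patient_id}: gapped frame length {len(seq)} does not match "
            f"sBm {sbm.allele_name} length {len(sbm.nt_gapped)}"
        )
    spans = region_spans if region_spans is not None else DEFAULT_REGION_SPANS
    if region_restriction is not None and region_restriction != "whole":
        lo, hi = region_span(region_restriction, spans)
    else:
        lo, hi = 1, len(seq)
    out: list[Mutation] = []
    for pos in range(lo, min(hi, len(seq)) + 1):
        g, p = sbm.nt_gapped[pos - 1], seq[pos - 1]
        if g in BASES and p in BASES and g != p:
            out.append(Mutation(nt_pos=pos, from_base=g, to_base=p,
                                region=region_of(pos, spans)))
    return out


def classify_sh(mut: Mutation, towg: GermlineAllele) -> bool:
    """True iff the TowG carries the mutation's introduced base at its position.

    A gap ('.') in the TowG at that position cannot share the mutation.
    """
    return towg.base_at(mut.nt_pos) == mut.to_base


def sh_scan(
    rearrs: Sequence["Rearrangement"],
    db: ReferenceDB,
    conserved_only: bool = False,
    region_restriction: str | None = None,
    region_spans: dict[str, tuple[int, int]] | None = None,
) -> tuple[list[SHRecord], list[tuple[str, Mutation]]]:
    """Classify every mutation of every sequence as SH or non-SH.

    Each mutation is compared against every reference allele other than the
    sequence's own sBm; one SHRecord is emitted per sharing allele, and a
    mutation shared by no allele contributes one non-SH entry.  With
    ``conserved_only`` only mutations at conserved positions of the sBm gene
    (positions where all its alleles agree) are considered at all.
    """
    sh_records: list[SHRecord] = []
    nonsh: list[tuple[str, Mutation]] = []
    conserved_cache: dict[str, set[int]] = {}
    for rearr in rearrs:
        muts = list_mutations(rearr, db, region_restriction, region_spans)
        if conserved_only:
            gene = gene_of(rearr.sbm_allele)
            if gene not in conserved_cache:
                conserved_cache[gene] = conserved_positions(db, gene)
            muts = [m for m in muts if m.nt_pos in conserved_cache[gene]]
        for mut in muts:
            shared = [
                name
                for name, allele in db.alleles.items()
                if name != rearr.sbm_allele and classify_sh(mut, allele)
            ]
            if shared:
                sh_records.extend(
                    SHRecord(rearr.patient_id, mut, name) for name in sorted(shared)
                )
            else:
                nonsh.append((rearr.patient_id, mut))
    return sh_records, nonsh


# ---------------------------------------------------------------------------
# annotation


def in_hotspot(
    sbm: GermlineAllele, nt_pos: int, motifs: Iterable[str] = DEFAULT_HOTSPOT_MOTIFS
) -> bool:
    """Whether a gapped position sits inside an SHM hotspot motif of its germline.

    The context is the ungapped sBm sequence; the position counts as a hotspot
    when any window matching one of the IUPAC motifs covers it.
    """
    ungapped = []
    target_idx = None
    for i, ch in enumerate(sbm.nt_gapped, start=1):
        if ch == ".":
            continue
        if i == nt_pos:
            target_idx = len(ungapped)
        ungapped.append(ch)
    if target_idx is None:
        raise ValueError(f"{sbm.allele_name} has a gap at position {nt_pos}")
    s = "".join(ungapped)
    for motif in motifs:
        w = len(motif)
        for start in range(max(0, target_idx - w + 1), min(target_idx, len(s) - w) + 1):
            window = s[start : start + w]
            if all(b in _IUPAC[m] for b, m in zip(window, motif)):
                return True
    return False


def _codon_chars(seq: str, codon: int) -> str:
    lo, hi = codon_span(codon)
    return seq[lo - 1 : hi] if hi <= len(seq) else ""


def _translate_codon(seq: str, codon: int) -> str | None:
    """Amino acid of a codon in a gapped sequence; None unless all 3 chars are bases."""
    chars = _codon_chars(seq, codon)
    if len(chars) != 3 or any(c not in BASES for c in chars):
        return None
    return str(Seq(chars).translate())


def annotate_mutation(
    mut: Mutation,
    rearr: "Rearrangement",
    db: ReferenceDB,
    towg: GermlineAllele | None = None,
    motifs: Iterable[str] = DEFAULT_HOTSPOT_MOTIFS,
) -> tuple[Mutation, dict[str, AAProperties | None]]:
    """Fill a mutation's annotation flags and amino-acid properties.

    Returns a new annotated Mutation plus the AAProperties of the codon
    containing the mutation in each of the three steps under investigation
    (sBm germline, sAm patient sequence, TowG germline; the TowG slot is None
    for a non-SH mutation without a TowG).  Codons not fully covered by bases
    yield None (undetermined).
    """
    sbm = db.get(rearr.sbm_allele)
    aa_sbm = _translate_codon(sbm.nt_gapped, mut.codon_number)
    aa_sam = _translate_codon(rearr.nt_gapped.upper(), mut.codon_number)
    aa_towg = _translate_codon(towg.nt_gapped, mut.codon_number) if towg is not None else None

    annotated = replace(
        mut,
        region=mut.region if mut.region is not None else region_of(mut.nt_pos),
        is_transition=frozenset({mut.from_base, mut.to_base}) in TRANSITIONS,
        is_replacement=(aa_sbm != aa_sam) if aa_sbm is not None and aa_sam is not None else None,
        in_hotspot=in_hotspot(sbm, mut.nt_pos, motifs),
    )
    props = {
        "sbm": aa_properties(aa_sbm) if aa_sbm is not None else None,
        "sam": aa_properties(aa_sam) if aa_sam is not None else None,
        "towg": aa_properties(aa_towg) if aa_towg is not None else None,
    }
    return annotated, props


# ---------------------------------------------------------------------------
# pairwise identity / dissimilarity


def compared_positions(a: str, b: str, positions: Iterable[int] | None = None) -> list[int]:
    """1-based positions where both gapped sequences carry an unambiguous base."""
    n = min(len(a), len(b))
    pool = range(1, n + 1) if positions is None else sorted(p for p in positions if p <= n)
    return [p for p in pool if a[p - 1] in BASES and b[p - 1] in BASES]


def pairwise_identity(a: str, b: str, positions: Iterable[int] | None = None) -> float:
    """Percent identity over positions where both sequences carry bases.

    Gaps and N are excluded from numerator and denominator; identical
    sequences give 100.0.  With no comparable positions returns float('nan').
    """
    comp = compared_positions(a, b, positions)
    if not comp:
        return float("nan")
    matches = sum(1 for p in comp if a[p - 1] == b[p - 1])
    return 100.0 * matches / len(comp)


def dissimilarity_count(a: str, b: str, positions: Iterable[int] | None = None) -> int:
    """Number of compared positions at which the two sequences differ."""
    return sum(1 for p in compared_positions(a, b, positions) if a[p - 1] != b[p - 1])


# ---------------------------------------------------------------------------
# dataset builders

_PROP_FIELDS = ("hydropathy", "volume", "chemical", "physicochemical", "charge")

SHPD_COLUMNS = [
    "patient_id", "subset", "sbm_allele", "gi_pct", "towg_allele", "sh_count",
    "nt_pos", "from_base", "to_base", "codon_number", "codon_sbm", "codon_sam",
    "aa_sbm", "aa_sam", "aa_towg", "region", "in_hotspot", "is_transition",
    "is_replacement",
] + [f"{p}_{step}" for p in _PROP_FIELDS for step in ("sbm", "sam", "towg")]

NONSHPD_COLUMNS = [
    "patient_id", "subset", "sbm_allele", "gi_pct",
    "nt_pos", "from_base", "to_base", "codon_number", "codon_sbm", "codon_sam",
    "aa_sbm", "aa_sam", "region", "in_hotspot", "is_transition", "is_replacement",
] + [f"{p}_{step}" for p in _PROP_FIELDS for step in ("sbm", "sam")] + [
    "new_property_functionality",
]

GSHD_COLUMNS = [
    "patient_id", "subset", "sam_id", "sbm_allele", "gi_sbm_sam",
    "towg_allele", "identity_towg_sbm", "sh_count",
]


def _prop_value(props: AAProperties | None, fld: str) -> str:
    return getattr(props, fld) if props is not None else UNDETERMINED


def _rearr_map(rearrs: Sequence["Rearrangement"]) -> dict[str, "Rearrangement"]:
    return {r.patient_id: r for r in rearrs}


def build_shpd(
    sh_records: Sequence[SHRecord],
    rearrs: Sequence["Rearrangement"],
    db: ReferenceDB,
    motifs: Iterable[str] = DEFAULT_HOTSPOT_MOTIFS,
) -> pd.DataFrame:
    """SH Position Dataset: one fully annotated row per (mutation, TowG) pair."""
    by_id = _rearr_map(rearrs)
    counts: dict[tuple[str, str], int] = {}
    for rec in sh_records:
        counts[(rec.patient_id, rec.towg_allele)] = counts.get(
            (rec.patient_id, rec.towg_allele), 0
        ) + 1
    rows = []
    for rec in sh_records:
        rearr = by_id[rec.patient_id]
        towg = db.get(rec.towg_allele)
        mut, props = annotate_mutation(rec.mutation, rearr, db, towg, motifs)
        row = {
            "patient_id": rec.patient_id,
            "subset": rearr.subset if rearr.subset is not None else "",
            "sbm_allele": rearr.sbm_allele,
            "gi_pct": rearr.germline_identity_pct,
            "towg_allele": rec.towg_allele,
            "sh_count": counts[(rec.patient_id, rec.towg_allele)],
            "nt_pos": mut.nt_pos,
            "from_base": mut.from_base,
            "to_base": mut.to_base,
            "codon_number": mut.codon_number,
            "codon_sbm": _codon_chars(db.get(rearr.sbm_allele).nt_gapped, mut.codon_number),
            "codon_sam": _codon_chars(rearr.nt_gapped.upper(), mut.codon_number),
            "aa_sbm": _translate_codon(db.get(rearr.sbm_allele).nt_gapped, mut.codon_number) or "X",
            "aa_sam": _translate_codon(rearr.nt_gapped.upper(), mut.codon_number) or "X",
            "aa_towg": _translate_codon(towg.nt_gapped, mut.codon_number) or "X",
            "region": mut.region or "",
            "in_hotspot": mut.in_hotspot,
            "is_transition": mut.is_transition,
            "is_replacement": mut.is_replacement,
        }
        for p in _PROP_FIELDS:
            for step in ("sbm", "sam", "towg"):
                row[f"{p}_{step}"] = _prop_value(props[step], p)
        rows.append(row)
    return pd.DataFrame(rows, columns=SHPD_COLUMNS)


def _functionality_classes_sharing(
    aa_sam: str | None, codon: int, db: ReferenceDB
) -> str:
    """Functionality classes (F/P/ORF) of germlines whose amino acid at this
    codon shares the sAm amino acid's IMGT chemical class."""
    if aa_sam is None:
        return UNDETERMINED
    target_class = aa_properties(aa_sam).chemical
    classes = set()
    for allele in db.alleles.values():
        aa = _translate_codon(allele.nt_gapped, codon)
        if aa is not None and aa_properties(aa).chemical == target_class:
            classes.add(allele.functionality)
    return "|".join(sorted(classes))


def build_nonshpd(
    nonsh: Sequence[tuple[str, Mutation]],
    rearrs: Sequence["Rearrangement"],
    db: ReferenceDB,
    motifs: Iterable[str] = DEFAULT_HOTSPOT_MOTIFS,
) -> pd.DataFrame:
    """Non-SH Position Dataset: one annotated row per unshared mutation."""
    by_id = _rearr_map(rearrs)
    rows = []
    for patient_id, mutation in nonsh:
        rearr = by_id[patient_id]
        mut, props = annotate_mutation(mutation, rearr, db, None, motifs)
        aa_sam = _translate_codon(rearr.nt_gapped.upper(), mut.codon_number)
        row = {
            "patient_id": patient_id,
            "subset": rearr.subset if rearr.subset is not None else "",
            "sbm_allele": rearr.sbm_allele,
            "gi_pct": rearr.germline_identity_pct,
            "nt_pos": mut.nt_pos,
            "from_base": mut.from_base,
            "to_base": mut.to_base,
            "codon_number": mut.codon_number,
            "codon_sbm": _codon_chars(db.get(rearr.sbm_allele).nt_gapped, mut.codon_number),
            "codon_sam": _codon_chars(rearr.nt_gapped.upper(), mut.codon_number),
            "aa_sbm": _translate_codon(db.get(rearr.sbm_allele).nt_gapped, mut.codon_number) or "X",
            "aa_sam": aa_sam or "X",
            "region": mut.region or "",
            "in_hotspot": mut.in_hotspot,
            "is_transition": mut.is_transition,
            "is_replacement": mut.is_replacement,
            "new_property_functionality": _functionality_classes_sharing(
                aa_sam, mut.codon_number, db
            ),
        }
        for p in _PROP_FIELDS:
            for step in ("sbm", "sam"):
                row[f"{p}_{step}"] = _prop_value(props[step], p)
        rows.append(row)
    return pd.DataFrame(rows, columns=NONSHPD_COLUMNS)


def build_gshd(
    sh_records: Sequence[SHRecord],
    rearrs: Sequence["Rearrangement"],
    db: ReferenceDB,
) -> pd.DataFrame:
    """Germlines-with-SH Dataset: one row per (patient sequence, TowG) pair.

    Carries the sBm, the sAm identifier, identity(sBm, sAm) (the reported
    GI%), the TowG, identity(TowG, sBm) over compared positions, and the
    number of SH mutations shared with that TowG.  This is the input of the
    towards analysis.
    """
    by_id = _rearr_map(rearrs)
    counts: dict[tuple[str, str], int] = {}
    for rec in sh_records:
        key = (rec.patient_id, rec.towg_allele)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for (patient_id, towg_name), n_sh in sorted(counts.items()):
        rearr = by_id[patient_id]
        sbm = db.get(rearr.sbm_allele)
        towg = db.get(towg_name)
        rows.append(
            {
                "patient_id": patient_id,
                "subset": rearr.subset if rearr.subset is not None else "",
                "sam_id": patient_id,
                "sbm_allele": rearr.sbm_allele,
                "gi_sbm_sam": rearr.germline_identity_pct,
                "towg_allele": towg_name,
                "identity_towg_sbm": round(
                    pairwise_identity(towg.nt_gapped, sbm.nt_gapped), 4
                ),
                "sh_count": n_sh,
            }
        )
    return pd.DataFrame(rows, columns=GSHD_COLUMNS)
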
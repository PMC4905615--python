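"""Shared fixtures: in-memory toy references and rearrangements."""

from __future__ import annotations

import re

import pytest

from towardsig.reference import GermlineAllele, ReferenceDB
from towardsig.rearrangements import Rearrangement

_SG = re.compile(r"^IGHV(\d)")


def make_allele(
    name: str,
    seq: str,
    functionality: str = "F",
    orphon: bool = False,
    partial_5prime: bool = False,
) -> GermlineAllele:
    gene = name.split("*", 1)[0]
    return GermlineAllele(
        allele_name=name,
        gene_name=gene,
        subgroup=int(_SG.match(name).group(1)),
        functionality=functionality,
        orphon=orphon,
        partial_5prime=partial_5prime,
        nt_gapped=seq.upper(),
    )


def make_db(alleles: list[GermlineAllele]) -> ReferenceDB:
    idx: dict[str, list[str]] = {}
    for a in alleles:
        idx.setdefault(a.gene_name, []).append(a.allele_name)
    return ReferenceDB(
        alleles={a.allele_name: a for a in alleles},
        gene_index={g: sorted(ns) for g, ns in idx.items()},
        version_label="toy",
    )


def make_rearr(
    patient_id: str,
    sbm_allele: str,
    nt_gapped: str,
    productive: bool = True,
    gi: float = 95.0,
    subset: str | None = None,
) -> Rearrangement:
    return Rearrangement(
        patient_id=patient_id,
        productive=productive,
        sbm_allele=sbm_allele,
        germline_identity_pct=gi,
        nt_gapped=nt_gapped.upper(),
        subset=subset,
    )


@pytest.fixture
def toy_db() -> ReferenceDB:
    """Three genes over two clans; IGHV1-1 has two alleles (one divergent column)."""
    return make_db(
        [
            make_allele("IGHV1-1*01", "ACGTACGTACGT"),
            make_allele("IGHV1-1*02", "ACGTACGAACGT"),  # differs at position 8 (T->A)
            make_allele("IGHV2-1*01", "ACGTTCGTACGA", functionality="P"),
            make_allele("IGHV3-1*01", "TCGTACGTACGG", functionality="ORF"),
        ]
    )
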
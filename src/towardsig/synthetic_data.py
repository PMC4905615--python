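"""Synthetic germline references and mutated cohorts with known ground truth.

The generator emulates the two real inputs of the pipeline at desk scale: a
hierarchical IGHV-like reference (alleles per gene, genes per subgroup,
subgroups per clan, mixed functionality) and a patient cohort whose
mutations are drawn with a configurable bias toward a designated target
germline gene.  Biased mutations copy the target allele's base at a position
where it differs from the sBm (guaranteed SH toward the target); unbiased
mutations introduce a base found in no germline at that column (guaranteed
non-SH).  A truth manifest records every planted mutation, so scan output
can be reconciled exactly.

All randomness flows through a single seeded NumPy generator; identical
specs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from towardsig.reference import ReferenceDB, GermlineAllele, write_reference
from towardsig.rearrangements import Rearrangement, write_rearrangements
from towardsig.shm import BASES, Mutation, pairwise_identity

_SUBGROUP_ORDER = (1, 2, 3, 4, 5, 6, 7)  # first three cover clans I, II, III


@dataclass
class SimSpec:
    """Parameters of one synthetic reference + cohort.

    Defaults mirror the structure of a real IGHV reference at toy scale:
    three subgroups (one per clan), a 120-nt gapped frame, and functionality
    fractions close to the observed pseudogene/ORF share of the human IGHV
    repertoire.  ``mutations_per_seq`` is either a fixed integer or
    ``("poisson", lam)``.
    """

    n_subgroups: int = 3
    genes_per_subgroup: int = 4
    alleles_per_gene: int = 2
    seq_len_nt: int = 120
    pseudo_fraction: float = 0.13
    orf_fraction: float = 0.04
    n_sequences: int = 30
    mutations_per_seq: int | tuple[str, float] = ("poisson", 6.0)
    target_gene: str = "IGHV1-1"
    bias_p: float = 0.8
    subset_labels: list[str] = field(default_factory=lambda: ["#4", "#201"])
    seed: int = 0
    allele_divergence: int = 2  # substituted positions per non-first allele
    gap_codon_prob: float = 0.3  # chance a gene carries one IMGT-gapped codon

    def __post_init__(self) -> None:
        if not 1 <= self.n_subgroups <= 7:
            raise ValueError("n_subgroups must be in 1..7")
        if self.genes_per_subgroup < 1 or self.alleles_per_gene < 1:
            raise ValueError("need at least one gene per subgroup and one allele per gene")
        if self.seq_len_nt < 30 or self.seq_len_nt % 3:
            raise ValueError("seq_len_nt must be a multiple of 3 and >= 30")
        for frac in (self.pseudo_fraction, self.orf_fraction, self.bias_p):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions and bias_p must lie in [0, 1]")
        if self.pseudo_fraction + self.orf_fraction > 1.0:
            raise ValueError("pseudo_fraction + orf_fraction must be <= 1")

    def draw_n_mutations(self, rng: np.random.Generator) -> int:
        if isinstance(self.mutations_per_seq, int):
            return self.mutations_per_seq
        kind, lam = self.mutations_per_seq
        if kind != "poisson":
            raise ValueError(f"unknown mutation-count distribution {kind!r}")
        return int(rng.poisson(lam))


def make_reference(spec: SimSpec, out_dir: str | Path | None = None) -> ReferenceDB:
    """Generate a hierarchical toy germline reference.

    Each gene descends from a random ancestor; additional alleles substitute
    ``allele_divergence`` positions, so genes have both conserved and
    non-conserved columns.  With probability ``gap_codon_prob`` a gene
    carries one '...'-gapped codon, emulating IMGT gap placement.  Writes
    ``reference.fasta`` and ``reference_meta.tsv`` when ``out_dir`` is given.
    """
    rng = np.random.default_rng(spec.seed)
    alleles: dict[str, GermlineAllele] = {}
    gene_index: dict[str, list[str]] = {}
    n_codons = spec.seq_len_nt // 3
    for sg in _SUBGROUP_ORDER[: spec.n_subgroups]:
        for g in range(1, spec.genes_per_subgroup + 1):
            gene = f"IGHV{sg}-{g}"
            ancestor = list(rng.choice(list(BASES), size=spec.seq_len_nt))
            if rng.random() < spec.gap_codon_prob:
                gap_codon = int(rng.integers(2, n_codons - 1))
                ancestor[3 * gap_codon : 3 * gap_codon + 3] = ["."] * 3
            names = []
            for a in range(1, spec.alleles_per_gene + 1):
                seq = list(ancestor)
                if a > 1:
                    non_gap = [i for i, ch in enumerate(seq) if ch != "."]
                    for i in rng.choice(non_gap, size=min(spec.allele_divergence, len(non_gap)),
                                        replace=False):
                        seq[i] = str(rng.choice([b for b in BASES if b != seq[i]]))
                u = rng.random()
                functionality = (
                    "P" if u < spec.pseudo_fraction
                    else "ORF" if u < spec.pseudo_fraction + spec.orf_fraction
                    else "F"
                )
                name = f"{gene}*{a:02d}"
                alleles[name] = GermlineAllele(
                    allele_name=name,
                    gene_name=gene,
                    subgroup=sg,
                    functionality=functionality,
                    orphon=False,
                    partial_5prime=False,
                    nt_gapped="".join(seq),
                )
                names.append(name)
            gene_index[gene] = names
    db = ReferenceDB(alleles=alleles, gene_index=gene_index,
                     version_label=f"synthetic-seed{spec.seed}")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reference(db, out / "reference.fasta", out / "reference_meta.tsv")
    return db


def _plant_nonsh(
    seq: list[str], db: ReferenceDB, mutated: set[int], rng: np.random.Generator,
    sbm_seq: str,
) -> tuple[int, str, str]:
    """Pick a position and base present in no germline at that column."""
    candidates = [i + 1 for i, ch in enumerate(sbm_seq) if ch in BASES and i + 1 not in mutated]
    for _ in range(1000):
        if not candidates:
            break
        pos = int(rng.choice(candidates))
        column = {a.base_at(pos) for a in db.alleles.values()} & set(BASES)
        free = sorted(set(BASES) - column)
        if free:
            return pos, sbm_seq[pos - 1], str(rng.choice(free))
        candidates.remove(pos)
    raise RuntimeError("no column admits a non-SH base; reference too saturated")


def make_cohort(
    db: ReferenceDB, spec: SimSpec, out_dir: str | Path | None = None
) -> tuple[list[Rearrangement], dict[str, str], dict]:
    """Generate a mutated cohort with planted SH bias toward ``spec.target_gene``.

    Each sequence starts from an sBm allele drawn from a gene other than the
    target.  Each mutation is, with probability ``bias_p``, a copy of the
    target allele's base at a position where sBm and target differ (a
    guaranteed SH toward the target); otherwise a base absent from every
    germline at that column (a guaranteed non-SH).  Returns the records, the
    patient->subset map, and the truth manifest; writes
    ``rearrangements.tsv``, ``subsets.tsv`` and ``truth.json`` under
    ``out_dir`` when given.
    """
    if spec.target_gene not in db.gene_index:
        raise ValueError(f"target gene {spec.target_gene!r} not in reference")
    rng = np.random.default_rng(spec.seed + 1)
    target = db.alleles_of(spec.target_gene)[0]
    sbm_pool = sorted(
        n for n, a in db.alleles.items() if a.gene_name != spec.target_gene
    )
    if not sbm_pool:
        raise ValueError("reference has no gene other than the target to draw sBm from")

    records: list[Rearrangement] = []
    subsets: dict[str, str] = {}
    manifest_seqs = []
    for i in range(spec.n_sequences):
        pid = f"P{i:04d}"
        sbm = db.get(str(rng.choice(sbm_pool)))
        diff = [
            p
            for p in range(1, len(sbm.nt_gapped) + 1)
            if sbm.base_at(p) in BASES
            and target.base_at(p) in BASES
            and sbm.base_at(p) != target.base_at(p)
        ]
        if spec.bias_p > 0 and not diff:
            raise ValueError(
                f"sBm {sbm.allele_name} identical to target {target.allele_name} "
                "over compared positions; cannot plant biased mutations"
            )
        n_mut = spec.draw_n_mutations(rng)
        seq = list(sbm.nt_gapped)
        mutated: set[int] = set()
        planted = []
        for _ in range(n_mut):
            avail = [p for p in diff if p not in mutated]
            if rng.random() < spec.bias_p and avail:
                pos = int(rng.choice(avail))
                frm, to = sbm.nt_gapped[pos - 1], target.base_at(pos)
                kind = "sh_target"
            else:
                pos, frm, to = _plant_nonsh(seq, db, mutated, rng, sbm.nt_gapped)
                kind = "nonsh"
            seq[pos - 1] = to
            mutated.add(pos)
            planted.append({"pos": pos, "from": frm, "to": to, "kind": kind})
        planted.sort(key=lambda d: d["pos"])
        nt = "".join(seq)
        subset = spec.subset_labels[i % len(spec.subset_labels)] if spec.subset_labels else None
        if subset is not None:
            subsets[pid] = subset
        records.append(
            Rearrangement(
                patient_id=pid,
                productive=True,
                sbm_allele=sbm.allele_name,
                germline_identity_pct=round(pairwise_identity(sbm.nt_gapped, nt), 4),
                nt_gapped=nt,
                subset=None,
                mutations=[
                    Mutation(nt_pos=d["pos"], from_base=d["from"], to_base=d["to"])
                    for d in planted
                ],
            )
        )
        manifest_seqs.append(
            {
                "patient_id": pid,
                "sbm_allele": sbm.allele_name,
                "subset": subset,
                "m_i": len(planted),
                "planted_sh_toward_target": sum(1 for d in planted if d["kind"] == "sh_target"),
                "planted_nonsh": sum(1 for d in planted if d["kind"] == "nonsh"),
                "mutations": planted,
            }
        )
    manifest = {
        "spec": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(spec).items()},
        "target_allele": target.allele_name,
        "n_sequences": len(records),
        "sequences": manifest_seqs,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_rearrangements(records, out / "rearrangements.tsv")
        with open(out / "subsets.tsv", "w") as fh:
            fh.write("patient_id\tsubset\n")
            for pid, subset in subsets.items():
                fh.write(f"{pid}\t{subset}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return records, subsets, manifest
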
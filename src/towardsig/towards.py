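"""Towards analysis: per-sequence scored lists, Borda-style aggregation, summaries.

Each patient sequence is a voter.  Its raw towards-list pairs every sharing
germline allele with an SH count; the scoring step rolls alleles up to genes
and converts counts into the movement score

    score_ik = SH_ik^2 / (M_i * maxSH_k * selSc_k)

where SH_ik is the mean SH count over gene k's alleles ("movement achieved"),
M_i the sequence's total mutation count ("available movement"), maxSH_k the
mean sBm/TowG dissimilarity over gene k's alleles ("initial movement
capability"), and selSc_k the number of candidate genes tied at the same
SH_ik ("selectivity").  Lists are homogenized to the union gene set,
min-max normalized to [0, 1], and aggregated as the arithmetic mean per
gene across voters; gene, clan and functionality summaries rescale the
resulting scores to percentages.

SH means and tie counts use exact Fraction arithmetic so selectivity ties
are never float artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy

from towardsig.reference import ReferenceDB, conserved_positions, gene_of
from towardsig.shm import SHRecord, dissimilarity_count, list_mutations

if TYPE_CHECKING:  # pragma: no cover
    from towardsig.rearrangements import Rearrangement

logger = logging.getLogger(__name__)

CLANS = ("I", "II", "III")
FUNCTIONALITY_CLASSES = ("F", "P", "ORF")


@dataclass
class RawList:
    """A voter's raw towards-list: per-allele SH counts plus metadata."""

    patient_id: str
    sbm_allele: str
    subset: str | None
    m_i: int
    elements: list[tuple[int, str]]  # (sh_count, towards_allele)

    @property
    def is_voter(self) -> bool:
        """A sequence with no mutations cannot vote; all-non-SH sequences can
        (they contribute zeros after homogenization)."""
        return self.m_i > 0


@dataclass
class ScoredList:
    """A voter's scored towards-list over genes (or alleles), one entry each."""

    patient_id: str
    sbm_allele: str
    subset: str | None
    m_i: int
    scores: dict[str, float]

    def genes(self) -> list[str]:
        return list(self.scores)


@dataclass
class ConsensusRanking:
    """Aggregated consensus over a voter group, sorted by mean score."""

    group_label: str
    n_voters: int
    elements: list[tuple[str, float, float]]  # (gene, mean_score, pct_of_total)
    clan_pct: dict[str, float] | None = None
    functionality_pct: dict[str, float] | None = None

    def mean_scores(self) -> dict[str, float]:
        return {g: s for g, s, _ in self.elements}

    def top(self) -> str | None:
        return self.elements[0][0] if self.elements else None


def build_raw_list(
    rearr: "Rearrangement",
    sh_records: Sequence[SHRecord],
    db: ReferenceDB,
    region_restriction: str | None = None,
) -> RawList:
    """Collect a sequence's SH counts per towards allele into its raw list.

    M_i is the sequence's total mutation count from list_mutations; a
    sequence with M_i = 0 is flagged non-voting.
    """
    counts: dict[str, int] = {}
    for rec in sh_records:
        if rec.patient_id == rearr.patient_id:
            counts[rec.towg_allele] = counts.get(rec.towg_allele, 0) + 1
    m_i = len(list_mutations(rearr, db, region_restriction))
    elements = [(n, allele) for allele, n in sorted(counts.items())]
    return RawList(
        patient_id=rearr.patient_id,
        sbm_allele=rearr.sbm_allele,
        subset=rearr.subset,
        m_i=m_i,
        elements=elements,
    )


def movement_score(
    sh: Fraction | int, m_i: int, max_sh: Fraction | int, sel_sc: int
) -> Fraction:
    """The movement score of one candidate: SH^2 / (M_i * maxSH * selSc).

    Exact rational arithmetic; callers convert to float only at the edge.
    """
    sh, max_sh = Fraction(sh), Fraction(max_sh)
    if m_i <= 0:
        raise ValueError("M_i must be positive")
    if max_sh <= 0:
        raise ValueError("maxSH must be positive")
    if sel_sc < 1:
        raise ValueError("selSc is self-inclusive and must be >= 1")
    return (sh * sh) / (m_i * max_sh * sel_sc)


def _candidate_sh_means(
    raw: RawList, db: ReferenceDB, exclude_sbm_gene: bool, level: str
) -> dict[str, Fraction]:
    """Exact mean SH count per candidate gene (or raw count per allele)."""
    allele_counts = {allele: n for n, allele in raw.elements}
    sbm_gene = gene_of(raw.sbm_allele)
    means: dict[str, Fraction] = {}
    if level == "gene":
        for gene in db.genes():
            if exclude_sbm_gene and gene == sbm_gene:
                continue
            alleles = db.gene_index[gene]
            total = sum(allele_counts.get(a, 0) for a in alleles)
            means[gene] = Fraction(total, len(alleles))
    elif level == "allele":
        for name in db.alleles:
            if name == raw.sbm_allele:
                continue
            if exclude_sbm_gene and gene_of(name) == sbm_gene:
                continue
            means[name] = Fraction(allele_counts.get(name, 0))
    else:
        raise ValueError(f"level must be 'gene' or 'allele', got {level!r}")
    return means


def score_list(
    raw: RawList,
    db: ReferenceDB,
    exclude_sbm_gene: bool = True,
    conserved_only: bool = False,
    level: str = "gene",
) -> ScoredList:
    """Score a raw towards-list, rolling alleles up to genes by default.

    Candidates with mean SH count 0 are omitted (their score is 0 and
    homogenization re-introduces them as zeros); candidates identical to the
    sBm over compared positions (maxSH = 0) are dropped with a log line.
    With ``conserved_only`` dissimilarities are restricted to conserved
    positions of the sBm gene.  ``level='allele'`` evaluates the same score
    per allele (used by the functionality summary).
    """
    if raw.m_i == 0:
        raise ValueError(f"{raw.patient_id}: M_i = 0; a mutation-free sequence cannot vote")
    sbm = db.get(raw.sbm_allele)
    positions = conserved_positions(db, gene_of(raw.sbm_allele)) if conserved_only else None

    sh_means = _candidate_sh_means(raw, db, exclude_sbm_gene, level)
    present = {k: v for k, v in sh_means.items() if v > 0}
    # selectivity: candidates tied at the same exact mean SH count
    selsc = {k: sum(1 for v in present.values() if v == sh) for k, sh in present.items()}

    scores: dict[str, float] = {}
    for cand, sh in sorted(present.items()):
        if level == "gene":
            alleles = [db.alleles[a] for a in db.gene_index[cand]]
            dis = Fraction(
                sum(dissimilarity_count(sbm.nt_gapped, a.nt_gapped, positions) for a in alleles),
                len(alleles),
            )
        else:
            dis = Fraction(
                dissimilarity_count(sbm.nt_gapped, db.alleles[cand].nt_gapped, positions)
            )
        if dis == 0:
            logger.info(
                "score_list %s: candidate %s identical to sBm over compared positions; dropped",
                raw.patient_id, cand,
            )
            continue
        scores[cand] = float(movement_score(sh, raw.m_i, dis, selsc[cand]))
    return ScoredList(
        patient_id=raw.patient_id,
        sbm_allele=raw.sbm_allele,
        subset=raw.subset,
        m_i=raw.m_i,
        scores=scores,
    )


def homogenize(lists: Sequence[ScoredList]) -> list[ScoredList]:
    """Give every list the identical union gene set, zero-filling new genes.

    Gene order is canonicalized lexicographically so outputs are byte-stable.
    """
    if not lists:
        raise ValueError("homogenize needs at least one list")
    union = sorted(set().union(*(sl.scores for sl in lists)))
    return [
        replace(sl, scores={g: sl.scores.get(g, 0.0) for g in union}) for sl in lists
    ]


def normalize_list(lg: ScoredList) -> ScoredList:
    """Min-max scale one list's scores to [0, 1].

    Degenerate cases: an all-zero list is a fixed point; a non-zero constant
    list maps to all ones (every candidate achieves the maximum movement).
    """
    if not lg.scores:
        return replace(lg, scores={})
    vals = lg.scores.values()
    smin, smax = min(vals), max(vals)
    if smax == smin:
        value = 0.0 if smax == 0.0 else 1.0
        return replace(lg, scores={g: value for g in lg.scores})
    return replace(
        lg, scores={g: (s - smin) / (smax - smin) for g, s in lg.scores.items()}
    )


def aggregate(lists: Sequence[ScoredList], group_label: str = "all") -> ConsensusRanking:
    """Borda-style aggregation: per-gene arithmetic mean across voters.

    Lists must be homogenized (identical gene sets).  The consensus is sorted
    by mean score descending, ties broken lexicographically by gene name;
    pct_of_total rescales mean scores to percentages of their sum.
    """
    if not lists:
        raise ValueError("aggregate needs at least one voter")
    gene_sets = {frozenset(sl.scores) for sl in lists}
    if len(gene_sets) > 1:
        raise ValueError("lists must be homogenized before aggregation")
    n = len(lists)
    genes = sorted(gene_sets.pop())
    means = {g: sum(sl.scores[g] for sl in lists) / n for g in genes}
    total = sum(means.values())
    elements = [
        (g, means[g], 100.0 * means[g] / total if total > 0 else 0.0)
        for g in sorted(genes, key=lambda g: (-means[g], g))
    ]
    return ConsensusRanking(group_label=group_label, n_voters=n, elements=elements)


def _rescale_to_pct(values: Mapping[str, float]) -> dict[str, float]:
    total = sum(values.values())
    if total <= 0:
        return {k: 0.0 for k in values}
    return {k: 100.0 * v / total for k, v in values.items()}


def clan_summary(
    cr: ConsensusRanking, db: ReferenceDB, mode: str = "avg"
) -> dict[str, float]:
    """Expected movement per clan, as percentages summing to 100.

    ``mode='avg'`` (default) averages the consensus mean scores over each
    clan's genes present in the union set; ``mode='sum'`` sums them.  The
    three clan values are then rescaled to percentages.
    """
    if mode not in ("avg", "sum"):
        raise ValueError(f"mode must be 'avg' or 'sum', got {mode!r}")
    by_clan: dict[str, list[float]] = {c: [] for c in CLANS}
    for gene, mean_score, _ in cr.elements:
        clan = db.clan_of_gene(gene)  # KeyError for unknown genes
        by_clan[clan].append(mean_score)
    raw = {
        c: (float(np.mean(v)) if mode == "avg" else float(np.sum(v))) if v else 0.0
        for c, v in by_clan.items()
    }
    return _rescale_to_pct(raw)


def functionality_summary(
    allele_lists: Sequence[ScoredList], db: ReferenceDB, mode: str = "avg"
) -> dict[str, float]:
    """Expected movement per functionality class (F/P/ORF), summing to 100.

    Takes allele-level scored lists (score_list with level='allele'),
    homogenizes and normalizes them, aggregates, then averages (or sums) the
    aggregated allele scores within each functionality class and rescales.
    """
    if mode not in ("avg", "sum"):
        raise ValueError(f"mode must be 'avg' or 'sum', got {mode!r}")
    normalized = [normalize_list(sl) for sl in homogenize(allele_lists)]
    cr = aggregate(normalized, group_label="functionality")
    by_class: dict[str, list[float]] = {c: [] for c in FUNCTIONALITY_CLASSES}
    for allele_name, mean_score, _ in cr.elements:
        by_class[db.get(allele_name).functionality].append(mean_score)
    raw = {
        c: (float(np.mean(v)) if mode == "avg" else float(np.sum(v))) if v else 0.0
        for c, v in by_class.items()
    }
    return _rescale_to_pct(raw)


@dataclass
class ClusterResult:
    """Hierarchical clustering of voter groups by their clan-movement vectors."""

    labels: list[str]
    linkage: np.ndarray

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def subset_clan_clustering(
    clan_vectors: Mapping[str, Sequence[float]],
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of subsets on their clan-percentage vectors.

    Default Euclidean distance with average linkage; returns the merge order
    and heights, serializable as Newick.
    """
    if len(clan_vectors) < 2:
        raise ValueError("clustering needs at least 2 subsets")
    labels = sorted(clan_vectors)
    X = np.array([list(clan_vectors[k]) for k in labels], dtype=float)
    Z = hierarchy.linkage(X, method=method, metric=metric)
    return ClusterResult(labels=labels, linkage=Z)
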
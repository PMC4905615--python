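"""Data-quality and subgroup-selection filters for integrated records.

Quality filters exclude unqualified sequences (unresolvable germline,
unproductive rearrangement, ambiguity characters, incomplete CDR1 and
upstream regions); selection filters direct the analysis to a stereotyped
subset, a germline-identity range, or a specific IGHV gene.  Rejection
reasons are attributed by first match in a fixed order so the report is
deterministic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from towardsig.reference import ReferenceDB, gene_of
from towardsig.rearrangements import Rearrangement
from towardsig.regions import DEFAULT_REGION_SPANS, region_span

logger = logging.getLogger(__name__)

#: fixed attribution order of quality-rejection reasons
QUALITY_REASONS = ("unresolved_germline", "unproductive", "ambiguity", "incomplete_cdr1_upstream")


@dataclass
class FilterConfig:
    """Configuration of both filter families; absent criteria are no-ops."""

    require_productive: bool = True
    reject_ambiguities: bool = True
    require_complete_cdr1_upstream: bool = True
    subset_whitelist: set[str] | None = None
    gene_whitelist: set[str] | None = None
    gi_pct_range: tuple[float, float] | None = None
    region_restriction: str | None = None
    region_spans: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SPANS)
    )

    def __post_init__(self) -> None:
        if self.gi_pct_range is not None:
            lo, hi = self.gi_pct_range
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"gi_pct_range must satisfy 0 <= low <= high <= 100, got {self.gi_pct_range}")
        if self.region_restriction is not None and self.region_restriction != "whole":
            region_span(self.region_restriction, self.region_spans)  # validates

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        kwargs = dict(d)
        if kwargs.get("subset_whitelist") is not None:
            kwargs["subset_whitelist"] = set(kwargs["subset_whitelist"])
        if kwargs.get("gene_whitelist") is not None:
            kwargs["gene_whitelist"] = set(kwargs["gene_whitelist"])
        if kwargs.get("gi_pct_range") is not None:
            kwargs["gi_pct_range"] = tuple(kwargs["gi_pct_range"])
        return cls(**kwargs)


def _analyzed_span(cfg: FilterConfig, frame_len: int) -> tuple[int, int]:
    if cfg.region_restriction is not None and cfg.region_restriction != "whole":
        lo, hi = region_span(cfg.region_restriction, cfg.region_spans)
        return lo, min(hi, frame_len)
    return 1, frame_len


def _has_ambiguity(rearr: Rearrangement, cfg: FilterConfig) -> bool:
    lo, hi = _analyzed_span(cfg, len(rearr.nt_gapped))
    return "N" in rearr.nt_gapped[lo - 1 : hi]


def _incomplete_cdr1_upstream(rearr: Rearrangement, db: ReferenceDB, cfg: FilterConfig) -> bool:
    """True when any FR1/CDR1 position lacks a base in the patient sequence
    although the sBm germline carries a base there."""
    sbm = db.get(rearr.sbm_allele)
    hi = min(region_span("CDR1", cfg.region_spans)[1], len(sbm.nt_gapped))
    seq = rearr.nt_gapped
    for pos in range(1, hi + 1):
        if sbm.base_at(pos) == ".":
            continue
        ch = seq[pos - 1] if pos <= len(seq) else "."
        if ch in (".", "N"):
            return True
    return False


def apply_quality_filters(
    records: Sequence[Rearrangement], cfg: FilterConfig, db: ReferenceDB
) -> tuple[list[Rearrangement], Counter]:
    """Apply the data-quality filters; returns kept records and a rejection tally.

    Each rejected record is counted once, under the first matching reason in
    the fixed order: unresolved germline, unproductive, ambiguity, incomplete
    CDR1+upstream.  ``sum(report.values()) + len(kept) == len(records)``.
    """
    kept: list[Rearrangement] = []
    report: Counter = Counter()
    for r in records:
        if r.sbm_allele not in db:
            report["unresolved_germline"] += 1
        elif cfg.require_productive and not r.productive:
            report["unproductive"] += 1
        elif cfg.reject_ambiguities and _has_ambiguity(r, cfg):
            report["ambiguity"] += 1
        elif cfg.require_complete_cdr1_upstream and _incomplete_cdr1_upstream(r, db, cfg):
            report["incomplete_cdr1_upstream"] += 1
        else:
            kept.append(r)
    return kept, report


def select_subgroup(
    records: Sequence[Rearrangement], cfg: FilterConfig
) -> list[Rearrangement]:
    """Keep records satisfying every configured selection criterion.

    Criteria (subset whitelist, gene whitelist on the sBm gene, germline
    identity range) combine as a conjunction; unset criteria are no-ops.
    """
    out = []
    for r in records:
        if cfg.subset_whitelist is not None and r.subset not in cfg.subset_whitelist:
            continue
        if cfg.gene_whitelist is not None and gene_of(r.sbm_allele) not in cfg.gene_whitelist:
            continue
        if cfg.gi_pct_range is not None:
            lo, hi = cfg.gi_pct_range
            if not lo <= r.germline_identity_pct <= hi:
                continue
        out.append(r)
    if cfg.subset_whitelist is not None and not out:
        logger.warning(
            "select_subgroup: no record matches subsets %s", sorted(cfg.subset_whitelist)
        )
    return out
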
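"""IMGT V-region delimitations in gapped nucleotide coordinates.

Positions are 1-based within the IMGT-gapped V-region frame; gap characters
('.') occupy positions but never carry a base.  The default spans are the
IMGT unique-numbering nucleotide delimitations for FR1 through FR3; CDR3 and
the junction are outside the analyzed frame.
"""

from __future__ import annotations

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

#: region -> (first, last) gapped nt position, inclusive
DEFAULT_REGION_SPANS: dict[str, tuple[int, int]] = {
    "FR1": (1, 78),
    "CDR1": (79, 114),
    "FR2": (115, 165),
    "CDR2": (166, 195),
    "FR3": (196, 312),
}


def region_of(nt_pos: int, spans: dict[str, tuple[int, int]] | None = None) -> str | None:
    """Return the V-region name containing a 1-based gapped nt position.

    Positions beyond the last configured span (e.g. past FR3) return None.
    """
    if nt_pos < 1:
        raise ValueError(f"nt position must be >= 1, got {nt_pos}")
    spans = spans if spans is not None else DEFAULT_REGION_SPANS
    for name, (lo, hi) in spans.items():
        if lo <= nt_pos <= hi:
            return name
    return None


def region_span(region: str, spans: dict[str, tuple[int, int]] | None = None) -> tuple[int, int]:
    spans = spans if spans is not None else DEFAULT_REGION_SPANS
    try:
        return spans[region]
    except KeyError:
        raise KeyError(f"unknown V region {region!r}; expected one of {sorted(spans)}") from None


def codon_number(nt_pos: int) -> int:
    """IMGT codon index of a gapped nt position (1-based, 3 nt per codon)."""
    if nt_pos < 1:
        raise ValueError(f"nt position must be >= 1, got {nt_pos}")
    return (nt_pos + 2) // 3


def codon_span(codon: int) -> tuple[int, int]:
    """First and last gapped nt position of a codon (inclusive)."""
    return 3 * (codon - 1) + 1, 3 * codon
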
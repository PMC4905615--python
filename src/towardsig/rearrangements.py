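"""Rearrangement (patient sequence) tables and the clinicobiological subset map.

The input dialect is a minimal AIRR-rearrangement-compatible TSV with columns
``sequence_id``, ``productive``, ``v_call``, ``v_identity``,
``sequence_alignment`` and optionally ``mutation_list`` (and ``subset`` on
re-exported intermediates).  ``sequence_id`` doubles as the patient unique
ID, the key on which all data sources are joined.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from towardsig.shm import Mutation

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["sequence_id", "productive", "v_call", "v_identity", "sequence_alignment"]
_MUTATION_TOKEN_RE = re.compile(r"^([acgt])(\d+)([acgt])$")
_TRUE = {"t", "true", "productive", "yes", "1"}
_FALSE = {"f", "false", "unproductive", "no", "0"}


@dataclass
class Rearrangement:
    """One patient IGHV sequence with its closest germline assignment.

    ``sbm_allele`` is the closest germline V allele (the "sequence before the
    mutation"); ``nt_gapped`` is the IMGT-gapped patient sequence (the
    "sequence after the mutation", sAm) over {A,C,G,T,N,.}.
    """

    patient_id: str
    productive: bool
    sbm_allele: str
    germline_identity_pct: float
    nt_gapped: str
    subset: str | None = None
    mutations: list[Mutation] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.germline_identity_pct <= 100.0:
            raise ValueError(
                f"{self.patient_id}: germline identity {self.germline_identity_pct} "
                "outside [0, 100]"
            )


@dataclass
class LoadReport:
    """Row-level problems collected while parsing a rearrangement table."""

    row_errors: list[tuple[str, str]] = field(default_factory=list)

    def add(self, patient_id: str, message: str) -> None:
        self.row_errors.append((patient_id, message))

    def __len__(self) -> int:
        return len(self.row_errors)


def parse_mutation_token(token: str) -> Mutation:
    """Parse a mutation token like 'a78g' (A->G at gapped nt position 78)."""
    m = _MUTATION_TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed mutation token {token!r}")
    return Mutation(nt_pos=int(m.group(2)), from_base=m.group(1).upper(),
                    to_base=m.group(3).upper())


def format_mutation_list(mutations: list[Mutation]) -> str:
    return ",".join(m.token for m in mutations)


def _parse_productive(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse productive flag {value!r}")


def load_rearrangements(
    path: str | Path, report: LoadReport | None = None
) -> list[Rearrangement]:
    """Load a rearrangement TSV into Rearrangement records.

    A missing required column is a hard error.  A malformed mutation token is
    a row-level error: the row is still loaded (with mutations unset) and the
    problem is recorded in ``report`` when one is passed.  Rows whose v_call
    does not resolve in the reference are loaded as-is; the quality filter
    flags them later.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rearrangement table {path} missing columns: {missing}")
    if report is None:
        report = LoadReport()
    records: list[Rearrangement] = []
    for _, row in df.iterrows():
        mutations: list[Mutation] | None = None
        if "mutation_list" in df.columns and row["mutation_list"].strip():
            try:
                mutations = [
                    parse_mutation_token(tok)
                    for tok in row["mutation_list"].split(",")
                    if tok.strip()
                ]
            except ValueError as exc:
                report.add(row["sequence_id"], str(exc))
                mutations = None
        subset = row["subset"].strip() if "subset" in df.columns and row["subset"].strip() else None
        records.append(
            Rearrangement(
                patient_id=row["sequence_id"],
                productive=_parse_productive(row["productive"]),
                sbm_allele=row["v_call"].strip(),
                germline_identity_pct=float(row["v_identity"]),
                nt_gapped=row["sequence_alignment"].strip().upper(),
                subset=subset,
                mutations=mutations,
            )
        )
    if report.row_errors:
        logger.warning("load_rearrangements: %d row-level errors", len(report.row_errors))
    return records


def write_rearrangements(records: list[Rearrangement], path: str | Path) -> None:
    """Write records back as the same TSV dialect (round-trips all fields)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.patient_id,
                "productive": "T" if r.productive else "F",
                "v_call": r.sbm_allele,
                "v_identity": r.germline_identity_pct,
                "sequence_alignment": r.nt_gapped,
                "mutation_list": format_mutation_list(r.mutations) if r.mutations else "",
                "subset": r.subset if r.subset is not None else "",
            }
        )
    columns = REQUIRED_COLUMNS + ["mutation_list", "subset"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def load_subsets(path: str | Path) -> dict[str, str]:
    """Load the two-column patient_id -> stereotyped-subset TSV.

    Consistent duplicates are tolerated; a patient mapped to two different
    subsets is a hard error.  An empty file yields an empty map with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"subset table {path} needs two columns (patient_id, subset)")
    id_col, subset_col = df.columns[:2]
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        pid, subset = row[id_col], row[subset_col]
        if pid in mapping and mapping[pid] != subset:
            raise ValueError(
                f"patient {pid!r} assigned to conflicting subsets "
                f"{mapping[pid]!r} and {subset!r}"
            )
        mapping[pid] = subset
    if not mapping:
        logger.warning("subset table %s is empty", path)
    return mapping


def integrate(
    rearrangements: list[Rearrangement], subsets: dict[str, str]
) -> list[Rearrangement]:
    """Join rearrangements with the subset map on patient unique ID.

    Never drops or reorders records; patients absent from the map keep their
    subset unset; map entries without a matching sequence are ignored (their
    count is logged).
    """
    seen = set()
    out = []
    for r in rearrangements:
        seen.add(r.patient_id)
        subset = subsets.get(r.patient_id, r.subset)
        out.append(
            Rearrangement(
                patient_id=r.patient_id,
                productive=r.productive,
                sbm_allele=r.sbm_allele,
                germline_identity_pct=r.germline_identity_pct,
                nt_gapped=r.nt_gapped,
                subset=subset,
                mutations=r.mutations,
            )
        )
    unmatched = len(set(subsets) - seen)
    if unmatched:
        logger.info("integrate: %d subset entries had no matching sequence", unmatched)
    return out
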
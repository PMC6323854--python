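"""Recruitment forests: participant records, wave assignment, analysis-set filters.

Respondent-driven sampling (RDS) produces recruitment *chains*: each chain
originates from a convenience-selected seed, and every other participant was
enrolled by exactly one recruiter using a limited number of coupons.  The
chains together form a forest.  This module builds and validates that forest
from a flat participant table, assigns recruitment waves (graph distance from
the seed; seeds are wave 0), and applies the analysis-set exclusions used in
dual-frame comparisons: drop seeds and wave-1 recruits (whose composition
still reflects the convenience seeds), drop incomplete questionnaires, and
drop chains that contribute only a single participant (a chain-clustered
variance needs at least two observations per retained chain).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError, LinkError, SchemaError, StructureError

RESERVED_COLUMNS = ("participant_id", "recruiter_id", "arm", "network_size", "complete")

DEFAULT_COUPON_LIMIT = 3


@dataclass(frozen=True)
class ParticipantRecord:
    """One row of a participant table.

    Parameters
    ----------
    participant_id:
        Opaque unique token.
    recruiter_id:
        Token of the recruiting participant, or ``None`` for seeds and for
        every registry-arm (PR) record.
    arm:
        ``"PR"`` (population-registry random sample) or ``"RDS"``.
    network_size:
        Reported number of target-population members the participant knows
        (the degree d_i used for inverse-degree weighting); RDS arm only,
        must be >= 1 when present.
    complete:
        Whether the questionnaire was completed (complete-case analyses keep
        only these).
    attributes:
        Mapping from attribute name to category label.
    """

    participant_id: str
    recruiter_id: str | None
    arm: str
    network_size: int | None = None
    complete: bool = True
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.arm not in ("PR", "RDS"):
            raise InputError(f"unknown arm {self.arm!r} for {self.participant_id!r}")
        if self.arm == "PR" and self.recruiter_id is not None:
            raise InputError(
                f"PR record {self.participant_id!r} must not have a recruiter"
            )
        if self.network_size is not None and self.network_size < 1:
            raise InputError(
                f"network_size must be >= 1, got {self.network_size} "
                f"for {self.participant_id!r}"
            )

    @property
    def is_seed(self) -> bool:
        return self.arm == "RDS" and self.recruiter_id is None


@dataclass
class RecruitmentForest:
    """A validated set of recruitment chains.

    ``graph`` is a directed forest (recruiter -> recruit); ``wave`` maps each
    participant to its distance from the seed of its chain; ``chain`` maps
    each participant to that seed's id.
    """

    records: dict[str, ParticipantRecord]
    graph: nx.DiGraph
    wave: dict[str, int]
    chain: dict[str, str]

    @property
    def seeds(self) -> list[str]:
        return sorted(pid for pid, r in self.records.items() if r.is_seed)

    @property
    def size(self) -> int:
        return len(self.records)

    def participants_at_wave(self, w: int) -> list[str]:
        return sorted(pid for pid, k in self.wave.items() if k == w)

    def chains(self) -> dict[str, list[str]]:
        """Chain seed id -> sorted member ids (seed included)."""
        out: dict[str, list[str]] = {}
        for pid, seed in self.chain.items():
            out.setdefault(seed, []).append(pid)
        return {seed: sorted(members) for seed, members in out.items()}


def build_forest(
    records: Sequence[ParticipantRecord],
    coupon_limit: int = DEFAULT_COUPON_LIMIT,
    strict: bool = False,
) -> RecruitmentForest:
    """Build and validate the recruitment forest from RDS records.

    PR-arm records are ignored (they carry no recruitment structure).  A seed
    that never completed the questionnaire and recruited nobody is dropped:
    it never entered the recruitment process (e.g. a seed who was invited but
    failed to participate).  An incomplete participant *with* recruits is
    kept as a structural node so its recruits keep their true wave; the
    completeness filter removes it from the analysis set later.

    Raises
    ------
    InputError
        Duplicate participant id.
    LinkError
        ``recruiter_id`` references an id not present in the table.
    StructureError
        The edges contain a cycle (including self-recruitment).

    Coupon-limit violations (> ``coupon_limit`` recruits) raise a warning by
    default since field data may contain them; ``strict=True`` turns them
    into :class:`StructureError`.
    """
    rds = [r for r in records if r.arm == "RDS"]
    by_id: dict[str, ParticipantRecord] = {}
    for r in rds:
        if r.participant_id in by_id:
            raise InputError(f"duplicate participant_id {r.participant_id!r}")
        by_id[r.participant_id] = r

    for r in rds:
        if r.recruiter_id is not None:
            if r.recruiter_id == r.participant_id:
                raise StructureError(
                    f"{r.participant_id!r} lists itself as recruiter (cycle)"
                )
            if r.recruiter_id not in by_id:
                raise LinkError(
                    f"recruiter_id {r.recruiter_id!r} of {r.participant_id!r} "
                    "not found in table"
                )

    graph = nx.DiGraph()
    graph.add_nodes_from(by_id)
    graph.add_edges_from(
        (r.recruiter_id, r.participant_id) for r in rds if r.recruiter_id is not None
    )
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise StructureError(f"recruitment links contain a cycle: {cycle}")

    # inactive seeds: incomplete, recruited nobody -> never part of any chain
    inactive = [
        pid
        for pid, r in by_id.items()
        if r.is_seed and not r.complete and graph.out_degree(pid) == 0
    ]
    for pid in inactive:
        graph.remove_node(pid)
        del by_id[pid]

    for pid in by_id:
        deg = graph.out_degree(pid)
        if deg > coupon_limit:
            msg = f"{pid!r} recruited {deg} > coupon limit {coupon_limit}"
            if strict:
                raise StructureError(msg)
            warnings.warn(msg, stacklevel=2)

    forest = RecruitmentForest(records=by_id, graph=graph, wave={}, chain={})
    return assign_waves(forest)


def assign_waves(forest: RecruitmentForest) -> RecruitmentForest:
    """Assign wave (distance from seed) and chain membership to every node.

    Seeds get wave 0; a recruit's wave is its recruiter's wave + 1.  A node
    with no seed ancestor (disconnected RDS record) raises
    :class:`StructureError`.
    """
    wave: dict[str, int] = {}
    chain: dict[str, str] = {}
    for seed in (pid for pid, r in forest.records.items() if r.is_seed):
        for pid, dist in nx.single_source_shortest_path_length(
            forest.graph, seed
        ).items():
            wave[pid] = dist
            chain[pid] = seed
    unreachable = set(forest.records) - set(wave)
    if unreachable:
        raise StructureError(
            f"nodes unreachable from any seed: {sorted(unreachable)}"
        )
    forest.wave = wave
    forest.chain = chain
    return forest


def filter_analysis_set(
    forest: RecruitmentForest, min_wave: int = 2
) -> set[str]:
    """Apply the analysis-set exclusions; returns the retained participant ids.

    Keeps participants with ``wave >= min_wave`` (default 2: seeds and the
    first wave still carry the convenience-seed composition; equilibrium is
    typically declared after one wave) and ``complete=True``, then drops any
    participant who is the sole survivor of its chain.  Deterministic and
    idempotent; may return an empty set.
    """
    survivors = {
        pid
        for pid, r in forest.records.items()
        if forest.wave[pid] >= min_wave and r.complete
    }
    per_chain: dict[str, int] = {}
    for pid in survivors:
        per_chain[forest.chain[pid]] = per_chain.get(forest.chain[pid], 0) + 1
    return {pid for pid in survivors if per_chain[forest.chain[pid]] >= 2}


# ---------------------------------------------------------------------------
# table I/O


def _parse_network_size(value) -> int | None:
    if value is None or (not isinstance(value, str) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    f = float(value)
    if not f.is_integer():
        raise SchemaError(f"network_size must be an integer, got {value!r}")
    return int(f)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot parse boolean from {value!r}")


def records_from_frame(df: pd.DataFrame) -> list[ParticipantRecord]:
    """Convert a participant table (DataFrame) to records.

    Required columns: ``participant_id, recruiter_id, arm, network_size,
    complete``; every other column is treated as a categorical attribute.
    Empty ``recruiter_id`` denotes a seed (RDS) or registry record (PR).
    """
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"participant table is missing columns: {missing}")
    attr_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        rid = d["recruiter_id"]
        if rid is None or (isinstance(rid, float) and math.isnan(rid)):
            rid = None
        else:
            rid = str(rid).strip() or None
        attrs = {}
        for c in attr_cols:
            v = d[c]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            attrs[c] = str(v)
        out.append(
            ParticipantRecord(
                participant_id=str(d["participant_id"]),
                recruiter_id=rid,
                arm=str(d["arm"]).strip().upper(),
                network_size=_parse_network_size(d["network_size"]),
                complete=_parse_bool(d["complete"]),
                attributes=attrs,
            )
        )
    return out


def read_participant_table(path, delimiter: str = ",") -> list[ParticipantRecord]:
    """Read a delimited participant table (UTF-8, header row)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df = df.replace("", None)
    return records_from_frame(df)


def write_participant_table(records: Iterable[ParticipantRecord], path,
                            delimiter: str = ",") -> None:
    records = list(records)
    attr_cols = sorted({k for r in records for k in r.attributes})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(list(RESERVED_COLUMNS) + attr_cols)
        for r in records:
            w.writerow(
                [
                    r.participant_id,
                    r.recruiter_id or "",
                    r.arm,
                    "" if r.network_size is None else r.network_size,
                    str(r.complete).lower(),
                ]
                + [r.attributes.get(c, "") for c in attr_cols]
            )


def write_edge_list(forest: RecruitmentForest, path, delimiter: str = ",") -> None:
    """Export recruiter -> recruit pairs as two-column delimited text."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["recruiter_id", "recruit_id"])
        for u, v in sorted(forest.graph.edges):
            w.writerow([u, v])
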
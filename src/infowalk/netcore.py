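"""Core domain types and file I/O for actors, referral networks, and information walks.

An *information walk* is the chronological sequence of actors visited by a
single walker (the motivating instance: the ordered list of physicians seen
by one patient). Unlike a path, a walk may revisit actors. Walks live on a
directed, count-weighted *referral network* whose actors carry categorical
metadata (specialty, hospital, residency hospital, and region — a
hospital-referral-region style market unit).

Timestamps are day-resolution: ISO-8601 dates in files, integer ordinal days
in memory. All time intervals follow the half-open convention ``[start, end)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

#: Reserved label for missing metadata; similarity indicators treat it as
#: matching nothing (including another UNKNOWN).
UNKNOWN = "__unknown__"

NETWORK_EDGE_COLUMNS = ("src", "dst", "count")
ACTOR_COLUMNS = ("actor_id", "specialty", "hospital", "residency_hospital", "region")
WALK_COLUMNS = ("walk_id", "step", "actor_id", "date", "rvu")


class NetworkFormatError(ValueError):
    """Raised for malformed or invariant-violating network/walk files."""


@dataclass(frozen=True)
class ActorProfile:
    """Metadata of one actor (physician) in the referral network."""

    actor_id: str
    specialty: str = UNKNOWN
    hospital: str = UNKNOWN
    residency_hospital: str = UNKNOWN
    region: str = UNKNOWN

    def __post_init__(self) -> None:
        for name in ("specialty", "hospital", "residency_hospital", "region"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty (use UNKNOWN sentinel)")
        if not self.actor_id:
            raise ValueError("actor_id must be non-empty")


@dataclass(frozen=True)
class Visit:
    """One visit record on a walk: actor seen, ordinal day, service intensity (RVU)."""

    actor_id: str
    day: int
    rvu: float = 0.0

    def __post_init__(self) -> None:
        if self.rvu < 0:
            raise ValueError(f"rvu must be non-negative, got {self.rvu}")


class ReferralNetwork:
    """Directed weighted graph of actors; edge weight = historical referral count.

    Parameters
    ----------
    actors
        Iterable of :class:`ActorProfile`; ids must be unique.
    edges
        Mapping ``(src, dst) -> count`` with positive integer counts.
        Self-loops are rejected; both endpoints must be known actors.
    period
        Optional half-open ``(start_day, end_day)`` interval the edge counts
        were accumulated over.
    """

    def __init__(
        self,
        actors: Iterable[ActorProfile],
        edges: Mapping[tuple[str, str], int],
        period: tuple[int, int] | None = None,
    ) -> None:
        self.actors: dict[str, ActorProfile] = {}
        for a in actors:
            if a.actor_id in self.actors:
                raise NetworkFormatError(f"duplicate actor_id {a.actor_id!r}")
            self.actors[a.actor_id] = a
        self.edges: dict[tuple[str, str], int] = {}
        for (src, dst), count in edges.items():
            if src == dst:
                raise NetworkFormatError(f"self-loop forbidden: {src!r}")
            if count <= 0:
                raise NetworkFormatError(
                    f"edge {src!r}->{dst!r} has non-positive count {count}"
                )
            for end in (src, dst):
                if end not in self.actors:
                    raise NetworkFormatError(f"edge endpoint {end!r} not in actor set")
            self.edges[(src, dst)] = int(count)
        self.period = period
        # undirected neighbor sets, used throughout feature/baseline code
        self._neighbors: dict[str, set[str]] = {a: set() for a in self.actors}
        for src, dst in self.edges:
            self._neighbors[src].add(dst)
            self._neighbors[dst].add(src)

    def __contains__(self, actor_id: str) -> bool:
        return actor_id in self.actors

    def __len__(self) -> int:
        return len(self.actors)

    def edge_count(self, src: str, dst: str) -> int:
        """Directed referral count on ``src -> dst`` (0 if absent)."""
        return self.edges.get((src, dst), 0)

    def neighbors(self, actor_id: str) -> frozenset[str]:
        """Undirected neighbor set of an actor."""
        return frozenset(self._neighbors[actor_id])

    def out_neighbors(self, actor_id: str) -> frozenset[str]:
        return frozenset(d for (s, d) in self.edges if s == actor_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferralNetwork):
            return NotImplemented
        return (
            self.actors == other.actors
            and self.edges == other.edges
            and self.period == other.period
        )


class InformationWalk:
    """A timestamped ordered visit sequence; revisits permitted.

    Invariants: at least one visit; timestamps non-decreasing.
    """

    def __init__(self, walk_id: str, visits: Iterable[Visit]) -> None:
        self.walk_id = walk_id
        self.visits: tuple[Visit, ...] = tuple(visits)
        if not self.visits:
            raise ValueError(f"walk {walk_id!r} has no visits")
        days = [v.day for v in self.visits]
        for i in range(1, len(days)):
            if days[i] < days[i - 1]:
                raise NetworkFormatError(
                    f"walk {walk_id!r}: timestamp decreases at step {i} "
                    f"({days[i]} < {days[i - 1]})"
                )

    def __len__(self) -> int:
        return len(self.visits)

    def __iter__(self) -> Iterator[Visit]:
        return iter(self.visits)

    @property
    def actor_sequence(self) -> tuple[str, ...]:
        return tuple(v.actor_id for v in self.visits)

    @property
    def actor_set(self) -> frozenset[str]:
        return frozenset(v.actor_id for v in self.visits)

    @property
    def start_day(self) -> int:
        return self.visits[0].day

    @property
    def end_day(self) -> int:
        return self.visits[-1].day

    def prefix(self, n: int) -> "InformationWalk":
        """The walk restricted to its first ``n`` visits (same walk_id)."""
        if not 1 <= n <= len(self.visits):
            raise ValueError(f"prefix length {n} out of range for walk of {len(self)}")
        return InformationWalk(self.walk_id, self.visits[:n])

    def observed_before(self, day: int) -> tuple[Visit, ...]:
        """Visits strictly before ``day`` (half-open convention)."""
        return tuple(v for v in self.visits if v.day < day)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InformationWalk):
            return NotImplemented
        return self.walk_id == other.walk_id and self.visits == other.visits

    def __repr__(self) -> str:
        return f"InformationWalk({self.walk_id!r}, {len(self)} visits)"


class WalkCorpus:
    """A set of information walks tied to the referral network they live on."""

    def __init__(self, walks: Iterable[InformationWalk], network: ReferralNetwork) -> None:
        self.walks: dict[str, InformationWalk] = {}
        for w in walks:
            if w.walk_id in self.walks:
                raise NetworkFormatError(f"duplicate walk_id {w.walk_id!r}")
            for v in w.visits:
                if v.actor_id not in network:
                    raise NetworkFormatError(
                        f"walk {w.walk_id!r} visits unknown actor {v.actor_id!r}"
                    )
            self.walks[w.walk_id] = w
        self.network = network

    def __len__(self) -> int:
        return len(self.walks)

    def __iter__(self) -> Iterator[InformationWalk]:
        return iter(self.walks.values())

    def __getitem__(self, walk_id: str) -> InformationWalk:
        return self.walks[walk_id]


# ---------------------------------------------------------------------------
# Day <-> date helpers


def day_from_date(text: str) -> int:
    """Parse an ISO-8601 date (or a plain integer day) into an ordinal day."""
    s = str(text).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return _dt.date.fromisoformat(s).toordinal()
    except ValueError as exc:
        raise NetworkFormatError(f"cannot parse date {text!r}") from exc


def date_from_day(day: int) -> str:
    """Ordinal day back to an ISO-8601 date string where representable
    (ordinals start at day 1 = 0001-01-01); other days stay plain integers,
    which :func:`day_from_date` reads back unchanged."""
    day = int(day)
    if day < 1:
        return str(day)
    return _dt.date.fromordinal(day).isoformat()


# ---------------------------------------------------------------------------
# File I/O: tab-separated, UTF-8, header row required.


def _read_tsv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise NetworkFormatError(f"{path}: malformed TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NetworkFormatError(f"{path}: missing columns {missing}")
    return df


def read_network(edge_path: str | Path, actor_path: str | Path) -> ReferralNetwork:
    """Read a referral network from an edge-list TSV plus an actor-metadata TSV.

    Edge list columns: ``src, dst, count``; metadata columns: ``actor_id,
    specialty, hospital, residency_hospital, region``. Self-loops, non-positive
    counts, and edges naming unknown actors are rejected.
    """
    edge_path, actor_path = Path(edge_path), Path(actor_path)
    adf = _read_tsv(actor_path, ACTOR_COLUMNS)
    actors = [
        ActorProfile(
            actor_id=row.actor_id,
            specialty=row.specialty or UNKNOWN,
            hospital=row.hospital or UNKNOWN,
            residency_hospital=row.residency_hospital or UNKNOWN,
            region=row.region or UNKNOWN,
        )
        for row in adf.itertuples(index=False)
    ]
    edf = _read_tsv(edge_path, NETWORK_EDGE_COLUMNS)
    edges: dict[tuple[str, str], int] = {}
    for lineno, row in enumerate(edf.itertuples(index=False), start=2):
        try:
            count = int(row.count)
        except ValueError:
            raise NetworkFormatError(
                f"{edge_path}: line {lineno}: non-integer count {row.count!r}"
            ) from None
        if row.src == row.dst:
            raise NetworkFormatError(f"{edge_path}: line {lineno}: self-loop {row.src!r}")
        if count <= 0:
            raise NetworkFormatError(
                f"{edge_path}: line {lineno}: non-positive count {count}"
            )
        edges[(row.src, row.dst)] = count
    try:
        return ReferralNetwork(actors, edges)
    except NetworkFormatError as exc:
        raise NetworkFormatError(f"{edge_path}: {exc}") from exc


def write_network(
    network: ReferralNetwork, edge_path: str | Path, actor_path: str | Path
) -> None:
    """Write a network to the TSV pair read by :func:`read_network` (lossless)."""
    edf = pd.DataFrame(
        [(s, d, c) for (s, d), c in sorted(network.edges.items())],
        columns=list(NETWORK_EDGE_COLUMNS),
    )
    edf.to_csv(edge_path, sep="\t", index=False)
    adf = pd.DataFrame(
        [
            (a.actor_id, a.specialty, a.hospital, a.residency_hospital, a.region)
            for a in sorted(network.actors.values(), key=lambda a: a.actor_id)
        ],
        columns=list(ACTOR_COLUMNS),
    )
    adf.to_csv(actor_path, sep="\t", index=False)


def read_walks(path: str | Path, network: ReferralNetwork) -> WalkCorpus:
    """Read a walk corpus from a one-visit-per-line TSV.

    Columns: ``walk_id, step, actor_id, date, rvu``. Visits are grouped by
    walk_id and ordered by step index; non-decreasing timestamps and actor
    membership in the network are validated.
    """
    path = Path(path)
    df = _read_tsv(path, WALK_COLUMNS)
    walks: list[InformationWalk] = []
    if len(df):
        df = df.assign(_step=df["step"].astype(int))
        for walk_id, grp in df.groupby("walk_id", sort=True):
            grp = grp.sort_values("_step")
            visits = [
                Visit(row.actor_id, day_from_date(row.date), float(row.rvu))
                for row in grp.itertuples(index=False)
            ]
            try:
                walks.append(InformationWalk(str(walk_id), visits))
            except NetworkFormatError as exc:
                raise NetworkFormatError(f"{path}: {exc}") from exc
    try:
        return WalkCorpus(walks, network)
    except NetworkFormatError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from exc


def write_walks(corpus_or_walks, path: str | Path) -> None:
    """Write walks to the TSV format read by :func:`read_walks`."""
    walks = list(corpus_or_walks)
    rows = [
        (w.walk_id, step, v.actor_id, date_from_day(v.day), v.rvu)
        for w in sorted(walks, key=lambda w: w.walk_id)
        for step, v in enumerate(w.visits)
    ]
    pd.DataFrame(rows, columns=list(WALK_COLUMNS)).to_csv(path, sep="\t", index=False)
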
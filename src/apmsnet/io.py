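"""Data model and text I/O for purification records, networks and references.

All on-disk formats are plain UTF-8 TSV:

* purification dialect ``purifications``: one row per experiment —
  ``experiment_id<TAB>bait<TAB>prey1<TAB>prey2...`` (zero preys is legal);
* purification dialect ``pairs``: one bait-prey pair per row —
  ``experiment_id<TAB>bait<TAB>prey``; rows sharing an experiment_id are
  merged into one purification;
* scored network: header then ``protein_a<TAB>protein_b<TAB>score`` with
  ``protein_a < protein_b`` lexicographically, rows in canonical rank order;
* reference set: two columns per row, one unordered pair each.

Lines starting with ``#`` are comments everywhere. Protein identifiers are
case-sensitive and whitespace-trimmed; no synonym or ortholog mapping is
ever applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Canonical unordered pair: a 2-tuple with the lexicographically smaller
#: identifier first.
Pair = tuple[str, str]


class ParseError(ValueError):
    """A malformed row in one of the TSV formats; names the line number."""


def make_pair(a: str, b: str) -> Pair:
    """Return the canonical unordered pair (min, max); reject self-pairs."""
    if a == b:
        raise ValueError(f"self-pair is not a valid protein pair: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Purification:
    """One AP-MS experiment: a tagged bait plus the prey set it pulled down.

    The bait never appears among its own preys — retrieving the tagged
    protein itself is structural, not interaction evidence — and the prey
    set is duplicate-free by construction.
    """

    experiment_id: str
    bait: str
    preys: frozenset[str]

    def __post_init__(self) -> None:
        if self.bait in self.preys:
            raise ValueError(
                f"purification {self.experiment_id!r}: bait {self.bait!r} "
                "must not be listed among its preys"
            )

    @property
    def members(self) -> frozenset[str]:
        """Bait and preys together — every protein seen in this experiment."""
        return self.preys | {self.bait}


@dataclass
class PurificationDataset:
    """An ordered collection of purifications with its protein universe."""

    purifications: list[Purification]

    def __post_init__(self) -> None:
        if not self.purifications:
            raise ValueError("a purification dataset must contain at least one record")

    @property
    def N(self) -> int:
        return len(self.purifications)

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.purifications:
            out.add(p.bait)
            out.update(p.preys)
        return frozenset(out)

    @property
    def baits(self) -> frozenset[str]:
        return frozenset(p.bait for p in self.purifications)

    @property
    def preys(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.purifications:
            out.update(p.preys)
        return frozenset(out)

    def summary(self) -> dict[str, int]:
        """Four headline statistics of a qualitative AP-MS data set."""
        return {
            "n_purifications": self.N,
            "n_distinct_baits": len(self.baits),
            "n_distinct_preys": len(self.preys),
            "n_proteins": len(self.proteins),
            "n_bait_prey_pairs": sum(len(p.preys) for p in self.purifications),
        }


@dataclass
class ScoredNetwork:
    """A symmetric weighted network stored as unordered-pair -> score.

    The canonical ranking order used everywhere (evaluation, serialization)
    is descending score with ties broken lexicographically by (min-id,
    max-id), so ranks are deterministic.
    """

    edges: dict[Pair, float]
    method_tag: str = ""

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-pair edge not allowed: {a!r}")
            if a > b:
                raise ValueError(f"edge key not canonical: ({a!r}, {b!r})")

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoredNetwork):
            return NotImplemented
        return self.edges == other.edges and self.method_tag == other.method_tag

    def ranked(self) -> list[tuple[Pair, float]]:
        """Edges in canonical rank order."""
        return sorted(self.edges.items(), key=lambda kv: (-kv[1], kv[0]))

    def top_pairs(self, k: int) -> list[Pair]:
        """The top-``k`` pairs of the canonical ranking (may be shorter)."""
        return [p for p, _ in self.ranked()[:k]]

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)


@dataclass
class ReferenceSet:
    """A set of experimentally validated binary interactions (e.g. Y2H)."""

    pairs: frozenset[Pair]
    name: str = ""

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers


def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split trimmed fields), skipping
    comment and blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, [f.strip() for f in line.split("\t")]


def read_purifications(
    path: str | Path, dialect: str = "purifications"
) -> PurificationDataset:
    """Load a purification TSV in either dialect.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"purifications"`` (one row per experiment, preys as extra columns)
        or ``"pairs"`` (one bait-prey pair per row; rows with the same
        experiment_id merge).

    Self-retrievals (bait listed among its own preys) are silently stripped;
    duplicate preys are collapsed. An empty file is an error: downstream
    scoring needs at least one purification.
    """
    path = Path(path)
    if dialect == "purifications":
        purifications = []
        for lineno, fields in _rows(path):
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected experiment_id, bait, preys..."
                )
            exp_id, bait, *preys = fields
            prey_set = frozenset(p for p in preys if p) - {bait}
            purifications.append(Purification(exp_id, bait, prey_set))
    elif dialect == "pairs":
        order: list[str] = []
        baits: dict[str, str] = {}
        preys_by_exp: dict[str, set[str]] = {}
        for lineno, fields in _rows(path):
            if len(fields) not in (2, 3) or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected experiment_id, bait[, prey]"
                )
            exp_id, bait = fields[0], fields[1]
            if exp_id not in baits:
                order.append(exp_id)
                baits[exp_id] = bait
                preys_by_exp[exp_id] = set()
            elif baits[exp_id] != bait:
                raise ParseError(
                    f"{path}:{lineno}: experiment {exp_id!r} has conflicting "
                    f"baits {baits[exp_id]!r} and {bait!r}"
                )
            if len(fields) == 3 and fields[2]:
                preys_by_exp[exp_id].add(fields[2])
        purifications = [
            Purification(e, baits[e], frozenset(preys_by_exp[e]) - {baits[e]})
            for e in order
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not purifications:
        raise ParseError(f"{path}: no purification records found")
    ds = PurificationDataset(purifications)
    logger.info("loaded %s: %s", path, ds.summary())
    return ds


def write_purifications(dataset: PurificationDataset, path: str | Path) -> None:
    """Write a dataset in the one-row-per-purification dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# experiment_id\tbait\tpreys...\n")
        for p in dataset.purifications:
            cols = [p.experiment_id, p.bait, *sorted(p.preys)]
            fh.write("\t".join(cols) + "\n")


_NETWORK_HEADER = "protein_a\tprotein_b\tscore"


def write_network(net: ScoredNetwork, path: str | Path) -> None:
    """Serialize a network in canonical rank order at full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        if net.method_tag:
            fh.write(f"# method: {net.method_tag}\n")
        fh.write(_NETWORK_HEADER + "\n")
        for (a, b), score in net.ranked():
            fh.write(f"{a}\t{b}\t{score!r}\n")


def read_network(path: str | Path) -> ScoredNetwork:
    """Read a scored-network TSV written by :func:`write_network`."""
    path = Path(path)
    method_tag = ""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# method:"):
            method_tag = first[len("# method:"):].strip()
    edges: dict[Pair, float] = {}
    for lineno, fields in _rows(path):
        if fields == _NETWORK_HEADER.split("\t"):
            continue
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        a, b, raw = fields
        try:
            score = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad score {raw!r}") from exc
        if math.isnan(score):
            raise ParseError(f"{path}:{lineno}: NaN score rejected")
        pair = make_pair(a, b)
        if pair in edges:
            raise ParseError(f"{path}:{lineno}: duplicate pair {pair}")
        edges[pair] = score
    return ScoredNetwork(edges, method_tag=method_tag)


def read_reference_set(path: str | Path, name: str = "") -> ReferenceSet:
    """Read a two-column pair list; self-pairs are dropped with a warning."""
    path = Path(path)
    pairs: set[Pair] = set()
    n_self = 0
    for lineno, fields in _rows(path):
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected exactly 2 columns")
        a, b = fields
        if a == b:
            n_self += 1
            continue
        pairs.add(make_pair(a, b))
    if n_self:
        logger.warning("%s: dropped %d self-pair row(s)", path, n_self)
    return ReferenceSet(frozenset(pairs), name=name or path.stem)


def write_reference_set(
    pairs: Iterable[Pair], path: str | Path, name: str = ""
) -> None:
    """Write unordered pairs as a two-column TSV (sorted, deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        if name:
            fh.write(f"# reference: {name}\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")
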
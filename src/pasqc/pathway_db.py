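"""Pathway gene sets with activator/repressor role (ARR) weights.

A pathway is an ordered collection of member genes, each carrying a discrete
topology weight in {-1, -0.5, 0, 0.5, 1}: positive for activators of the
pathway's output, negative for repressors, with 0.5 magnitudes for weak or
ambiguous roles.  The on-disk format is a three-column TSV
(``pathway<TAB>gene<TAB>arr``) with a header row; the standard GMT gene-set
format can be imported by assigning every gene a uniform default role.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ALLOWED_ARR",
    "GeneRole",
    "Pathway",
    "PathwayDB",
    "PathwayParseError",
    "PathwayValidationError",
    "read_pathway_table",
    "write_pathway_table",
    "import_gmt",
]

#: The discrete activator/repressor role weights a gene may carry.
ALLOWED_ARR = (-1.0, -0.5, 0.0, 0.5, 1.0)


class PathwayValidationError(ValueError):
    """An in-memory pathway object violates a structural invariant."""


class PathwayParseError(ValueError):
    """A pathway file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class GeneRole:
    """A pathway member: a gene identifier and its ARR weight."""

    gene: str
    arr: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise PathwayValidationError("gene identifier must be non-empty")
        if float(self.arr) not in ALLOWED_ARR:
            raise PathwayValidationError(
                f"arr must be one of {ALLOWED_ARR}, got {self.arr!r}"
            )
        object.__setattr__(self, "arr", float(self.arr))


class Pathway:
    """A named, ordered set of :class:`GeneRole` members.

    Gene identifiers are opaque, case-sensitive strings and must be unique
    within a pathway.
    """

    def __init__(self, name: str, members: Iterable[GeneRole]):
        members = tuple(members)
        if not name:
            raise PathwayValidationError("pathway name must be non-empty")
        if not members:
            raise PathwayValidationError(f"pathway {name!r} has no members")
        genes = [m.gene for m in members]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise PathwayValidationError(
                f"pathway {name!r} lists duplicate gene(s): {dupes}"
            )
        self.name = name
        self.members = members

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(m.gene for m in self.members)

    def arr_map(self) -> dict[str, float]:
        return {m.gene: m.arr for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pathway):
            return NotImplemented
        return self.name == other.name and self.members == other.members

    def __repr__(self) -> str:
        return f"Pathway({self.name!r}, {len(self.members)} genes)"


class PathwayDB:
    """A collection of pathways keyed by unique name."""

    def __init__(self, pathways: Iterable[Pathway]):
        pathways = list(pathways)
        if not pathways:
            raise PathwayValidationError("a PathwayDB must hold at least one pathway")
        self._pathways: dict[str, Pathway] = {}
        for p in pathways:
            if p.name in self._pathways:
                raise PathwayValidationError(f"duplicate pathway name {p.name!r}")
            self._pathways[p.name] = p

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._pathways)

    def __getitem__(self, name: str) -> Pathway:
        return self._pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self._pathways

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._pathways.values())

    def __len__(self) -> int:
        return len(self._pathways)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return self.names == other.names and all(
            self[n] == other[n] for n in self.names
        )

    def __repr__(self) -> str:
        n_genes = sum(len(p) for p in self)
        return f"PathwayDB({len(self)} pathways, {n_genes} gene roles)"

    def all_genes(self) -> tuple[str, ...]:
        """All distinct gene identifiers, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self:
            for g in p.genes:
                seen.setdefault(g)
        return tuple(seen)


_HEADER = ("pathway", "gene", "arr")


def read_pathway_table(path: str | Path) -> PathwayDB:
    """Read a three-column pathway TSV (``pathway  gene  arr``) into a DB.

    Row order within a pathway is preserved.  Malformed rows raise
    :class:`PathwayParseError` naming the offending line number; invariant
    violations (bad ARR, duplicate genes) raise
    :class:`PathwayValidationError`.
    """
    path = Path(path)
    rows: dict[str, list[GeneRole]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PathwayParseError(f"{path}: empty file, expected header {_HEADER}")
        if tuple(h.strip() for h in header) != _HEADER:
            raise PathwayParseError(
                f"{path}: line 1: expected header {_HEADER}, got {tuple(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) != 3:
                raise PathwayParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(row)}"
                )
            pw, gene, arr_s = (c.strip() for c in row)
            try:
                arr = float(arr_s)
            except ValueError:
                raise PathwayParseError(
                    f"{path}: line {lineno}: arr {arr_s!r} is not a number"
                ) from None
            if arr not in ALLOWED_ARR:
                raise PathwayValidationError(
                    f"{path}: line {lineno}: arr {arr} not in {ALLOWED_ARR}"
                )
            bucket = rows.setdefault(pw, [])
            if any(m.gene == gene for m in bucket):
                raise PathwayValidationError(
                    f"{path}: line {lineno}: duplicate gene {gene!r} "
                    f"in pathway {pw!r}"
                )
            bucket.append(GeneRole(gene, arr))
    return PathwayDB(Pathway(name, members) for name, members in rows.items())


def write_pathway_table(db: PathwayDB, path: str | Path) -> None:
    """Write a DB as a three-column TSV re-readable by :func:`read_pathway_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for p in db:
            for m in p.members:
                writer.writerow([p.name, m.gene, _fmt_arr(m.arr)])


def _fmt_arr(arr: float) -> str:
    # keep -1.0 as "-1.0" etc. so the file round-trips through float() exactly
    return repr(arr)


def import_gmt(path: str | Path, default_arr: float = 1.0) -> PathwayDB:
    """Import a standard GMT gene-set file, assigning every gene ``default_arr``.

    GMT carries no topology information, so all genes in a set receive the
    same role weight; with the default of 1.0 the pathway activation score
    reduces to a plain signed sum of flagged log-ratios over the set.
    """
    if float(default_arr) not in ALLOWED_ARR:
        raise PathwayValidationError(
            f"default_arr must be one of {ALLOWED_ARR}, got {default_arr!r}"
        )
    path = Path(path)
    pathways: list[Pathway] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PathwayParseError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise PathwayValidationError(
                    f"{path}: line {lineno}: gene set {name!r} is empty"
                )
            pathways.append(
                Pathway(name, (GeneRole(g, float(default_arr)) for g in genes))
            )
    return PathwayDB(pathways)
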
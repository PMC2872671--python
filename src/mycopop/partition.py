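"""Strain-to-population/lineage assignments."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import PartitionError


@dataclass
class LineagePartition:
    """Maps each strain to exactly one (population, lineage) pair."""

    assignments: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise PartitionError("empty partition")
        for sid, pair in self.assignments.items():
            if len(pair) != 2 or not pair[0] or not pair[1]:
                raise PartitionError(f"strain {sid!r}: need nonempty (population, lineage)")

    def population(self, strain_id: str) -> str:
        return self._get(strain_id)[0]

    def lineage(self, strain_id: str) -> str:
        return self._get(strain_id)[1]

    def _get(self, strain_id: str) -> tuple[str, str]:
        try:
            return self.assignments[strain_id]
        except KeyError:
            raise PartitionError(f"strain {strain_id!r} has no population/lineage assignment")

    @property
    def strains(self) -> list[str]:
        return list(self.assignments)

    @property
    def populations(self) -> list[str]:
        return sorted({p for p, _ in self.assignments.values()})

    @property
    def lineages(self) -> list[str]:
        return sorted({l for _, l in self.assignments.values()})

    def strains_in_population(self, population: str) -> list[str]:
        return [s for s, (p, _) in self.assignments.items() if p == population]

    def strains_in_lineage(self, lineage: str) -> list[str]:
        out = [s for s, (_, l) in self.assignments.items() if l == lineage]
        if not out:
            raise PartitionError(f"lineage {lineage!r} has no strains")
        return out


def read_partition(path: str | Path) -> LineagePartition:
    """Read a TSV with columns strain, population, lineage (header required)."""
    assignments: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["strain", "population", "lineage"]:
            raise PartitionError(
                f"{path}: expected header 'strain\\tpopulation\\tlineage', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PartitionError(f"{path}:{lineno}: need 3 tab-separated fields")
            sid, pop, lin = parts[:3]
            if sid in assignments:
                raise PartitionError(f"{path}:{lineno}: duplicate strain {sid!r}")
            assignments[sid] = (pop, lin)
    return LineagePartition(assignments)


def write_partition(partition: LineagePartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tpopulation\tlineage\n")
        for sid, (pop, lin) in partition.assignments.items():
            fh.write(f"{sid}\t{pop}\t{lin}\n")
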
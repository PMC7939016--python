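"""Gene sets and the GMT (gene-matrix-transposed) text format.

Ships two small reference collections used on real panel data: a
reconstructed immune-enrichment-signature (IES) collection of cell-type /
process sets, and the 18-gene T-cell-inflamed expression profile.  The IES
membership is a reconstruction from the public literature, not the original
supplement, and is meant to be swapped for a curated GMT in real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GeneSet", "read_gmt", "write_gmt", "load_ies_sets", "load_gep_genes",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with optional per-gene weights."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    weights: Mapping[str, float] | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        if self.weights is not None and set(self.weights) != set(self.genes):
            raise ValueError(f"weights of {self.name!r} do not match its members")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        universe = set(universe)
        kept = tuple(g for g in self.genes if g in universe)
        if not kept:
            raise ValueError(f"gene set {self.name!r} has no overlap with the universe")
        w = {g: self.weights[g] for g in kept} if self.weights else None
        return GeneSet(self.name, kept, self.description, w)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and ≥1 gene")
        genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
        sets.append(GeneSet(parts[0], genes, parts[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description or "na", *s.genes]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("radresponse").joinpath("data", name)))


def load_ies_sets() -> list[GeneSet]:
    """Reconstructed immune enrichment signature (IES) cell-type/process sets."""
    return read_gmt(_data_path("ies_reconstructed.gmt"))


def load_gep_genes() -> GeneSet:
    """The 18-gene T-cell-inflamed expression profile."""
    genes = tuple(
        g for g in _data_path("tcell_inflamed_gep.txt").read_text().split() if g
    )
    return GeneSet("TCELL_INFLAMED_GEP", genes,
                   "18-gene T-cell-inflamed expression profile")
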
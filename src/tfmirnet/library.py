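"""Putative-regulation libraries (TF2gene, TF2miR, miR2gene).

A regulation library is a typed edge list of forward-engineered (sequence /
binding-site derived) regulator->target relationships.  Three classes exist:

* ``TF2gene``  — TF -> protein-coding gene (the target may itself be a TF);
* ``TF2miR``   — TF -> miRNA gene (transcriptional control of the miRNA);
* ``miR2gene`` — miRNA -> protein-coding gene (including miRNA -> TF).

miRNA -> miRNA regulation does not exist in this model, and protein-coding
genes that are not TFs have no outgoing edges.  Membership of a pair
``(regulator, target)`` in a library is the binary design indicator used by
the regression engines (1 if present, 0 otherwise).

Files are plain tab-separated text with two identifier columns
(``regulator_id``, ``target_id``); lines starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .names import consolidate_mirna_name, looks_like_mirna

logger = logging.getLogger(__name__)

__all__ = ["NodeType", "EdgeClass", "RegulationEdge", "RegulationLibrary", "load_library"]


class NodeType(str, Enum):
    TF = "TF"
    MIRNA = "miRNA"
    GENE = "gene"


class EdgeClass(str, Enum):
    TF2GENE = "TF2gene"
    TF2MIR = "TF2miR"
    MIR2GENE = "miR2gene"

    @property
    def regulator_type(self) -> NodeType:
        return NodeType.MIRNA if self is EdgeClass.MIR2GENE else NodeType.TF

    @property
    def target_type(self) -> NodeType:
        # TF2gene / miR2gene targets are protein-coding genes; whether a given
        # target is additionally a TF is only known once libraries are merged.
        return NodeType.MIRNA if self is EdgeClass.TF2MIR else NodeType.GENE


@dataclass(frozen=True)
class RegulationEdge:
    """One putative regulator->target relationship of a given class."""

    regulator_id: str
    target_id: str
    edge_class: EdgeClass

    def __post_init__(self) -> None:
        if not self.regulator_id or not self.target_id:
            raise ValueError("empty identifier in regulation edge")
        if self.regulator_id == self.target_id:
            raise ValueError(f"self-regulation edge {self.regulator_id!r} not allowed")

    @property
    def regulator_type(self) -> NodeType:
        return self.edge_class.regulator_type

    @property
    def target_type(self) -> NodeType:
        return self.edge_class.target_type


class RegulationLibrary:
    """An immutable set of same-class regulation edges with fast lookups.

    miRNA identifiers (regulators of ``miR2gene``, targets of ``TF2miR``) are
    consolidated to root form on construction; duplicate pairs collapse with a
    logged count.
    """

    def __init__(self, edge_class: EdgeClass, pairs: Iterable[tuple[str, str]]):
        self.edge_class = EdgeClass(edge_class)
        seen: set[tuple[str, str]] = set()
        ordered: list[tuple[str, str]] = []
        n_dup = 0
        for reg, tgt in pairs:
            reg, tgt = self._normalise(reg.strip(), tgt.strip())
            self._validate_pair(reg, tgt)
            if (reg, tgt) in seen:
                n_dup += 1
                continue
            seen.add((reg, tgt))
            ordered.append((reg, tgt))
        if n_dup:
            logger.info("%s library: collapsed %d duplicate pair(s)", self.edge_class.value, n_dup)
        self._pairs = tuple(sorted(ordered))
        self._pair_set = seen
        self._targets: dict[str, tuple[str, ...]] = {}
        self._regulators: dict[str, tuple[str, ...]] = {}
        by_reg: dict[str, list[str]] = defaultdict(list)
        by_tgt: dict[str, list[str]] = defaultdict(list)
        for reg, tgt in self._pairs:
            by_reg[reg].append(tgt)
            by_tgt[tgt].append(reg)
        self._targets = {k: tuple(v) for k, v in by_reg.items()}
        self._regulators = {k: tuple(v) for k, v in by_tgt.items()}

    def _normalise(self, reg: str, tgt: str) -> tuple[str, str]:
        if self.edge_class is EdgeClass.MIR2GENE:
            reg = consolidate_mirna_name(reg)
        elif self.edge_class is EdgeClass.TF2MIR:
            tgt = consolidate_mirna_name(tgt)
        return reg, tgt

    def _validate_pair(self, reg: str, tgt: str) -> None:
        if not reg or not tgt:
            raise ValueError("empty identifier")
        if reg == tgt:
            raise ValueError(f"self-regulation {reg!r} not allowed")
        # Gene-class targets must not be miRNA transcripts (no miRNA->miRNA,
        # and TFs regulate miRNAs only through the TF2miR class).
        if self.edge_class in (EdgeClass.MIR2GENE, EdgeClass.TF2GENE) and looks_like_mirna(tgt):
            raise ValueError(
                f"{self.edge_class.value} target {tgt!r} looks like a miRNA; "
                f"{'miRNA->miRNA edges are forbidden' if self.edge_class is EdgeClass.MIR2GENE else 'use TF2miR for TF->miRNA edges'}"
            )
        if self.edge_class in (EdgeClass.TF2GENE, EdgeClass.TF2MIR) and looks_like_mirna(reg):
            raise ValueError(f"{self.edge_class.value} regulator {reg!r} looks like a miRNA")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._pair_set

    def __iter__(self) -> Iterator[RegulationEdge]:
        for reg, tgt in self._pairs:
            yield RegulationEdge(reg, tgt, self.edge_class)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RegulationLibrary)
            and self.edge_class is other.edge_class
            and self._pairs == other._pairs
        )

    def __repr__(self) -> str:
        return f"RegulationLibrary({self.edge_class.value}, {len(self)} edges)"

    # -- lookups ------------------------------------------------------------
    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return self._pairs

    @property
    def regulators(self) -> tuple[str, ...]:
        return tuple(sorted(self._targets))

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(sorted(self._regulators))

    def targets_of(self, regulator: str) -> tuple[str, ...]:
        return self._targets.get(regulator, ())

    def regulators_of(self, target: str) -> tuple[str, ...]:
        return self._regulators.get(target, ())

    # -- file I/O -----------------------------------------------------------
    @classmethod
    def load(cls, path: str | Path, edge_class: EdgeClass) -> "RegulationLibrary":
        """Read a two-column tab-separated edge list; ``#`` lines are comments."""
        path = Path(path)
        pairs: list[tuple[str, str]] = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise ValueError(f"{path}:{lineno}: expected two tab-separated identifiers, got {line!r}")
                pairs.append((fields[0], fields[1]))
        if not pairs:
            logger.warning("%s: empty %s library", path, EdgeClass(edge_class).value)
        try:
            return cls(edge_class, pairs)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# regulator_id\ttarget_id\n")
            for reg, tgt in self._pairs:
                fh.write(f"{reg}\t{tgt}\n")


def load_library(path: str | Path, edge_class: EdgeClass) -> RegulationLibrary:
    """Functional alias for :meth:`RegulationLibrary.load`."""
    return RegulationLibrary.load(path, edge_class)
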
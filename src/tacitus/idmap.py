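"""Probe-to-standard-identifier mapping.

A mapping table keeps only probes with a non-null identifier in the chosen
namespace. Applying it to a matrix renames mapped probes, drops unmapped
ones, and resolves many-to-one collisions with a configurable policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from tacitus.types import ExpressionMatrix, PlatformAnnotation, TacitusError

COLLISION_POLICIES = ("mean", "first", "max_mean")


@dataclass
class MappingTable:
    """Probe id -> target identifier for one namespace; no null targets."""

    namespace: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for probe, target in self.mapping.items():
            if target is None or target == "":
                raise TacitusError(f"null target for probe {probe!r}")

    def __len__(self) -> int:
        return len(self.mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for probe, target in self.mapping.items():
                fh.write(f"{probe}\t{target}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, namespace: str = "") -> "MappingTable":
        mapping: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\r\n")
                if not line:
                    continue
                probe, _, target = line.partition("\t")
                mapping[probe] = target
        return cls(namespace=namespace, mapping=mapping)


def build_mapping_table(annotation: PlatformAnnotation, namespace: str) -> MappingTable:
    """Collect probes with a non-null identifier in ``namespace``."""
    if namespace not in annotation.namespaces:
        raise TacitusError(
            f"unknown namespace {namespace!r}; available: {annotation.namespaces}"
        )
    mapping: dict[str, str] = {}
    for probe in annotation.probe_ids:
        target = annotation.mapping.get(probe, {}).get(namespace)
        if target is not None:
            mapping[probe] = target
    return MappingTable(namespace=namespace, mapping=mapping)


def apply_mapping(
    matrix: ExpressionMatrix,
    table: MappingTable,
    collision_policy: str = "mean",
) -> ExpressionMatrix:
    """Rename mapped probes and drop unmapped ones.

    When two or more probes map to the same target, their rows are combined
    per ``collision_policy``: ``mean`` (element-wise mean), ``first`` (first
    probe in matrix order) or ``max_mean`` (probe with highest row mean).
    Output row order is the first-occurrence order of the targets.
    """
    if collision_policy not in COLLISION_POLICIES:
        raise TacitusError(
            f"unknown collision policy {collision_policy!r}; "
            f"expected one of {COLLISION_POLICIES}"
        )
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for r, probe in enumerate(matrix.probe_ids):
        target = table.mapping.get(probe)
        if target is None:
            continue
        if target not in groups:
            groups[target] = []
            order.append(target)
        groups[target].append(r)
    if not order:
        raise TacitusError("no probes mapped")

    out = np.empty((len(order), matrix.n_samples), dtype=float)
    for i, target in enumerate(order):
        rows = groups[target]
        if len(rows) == 1 or collision_policy == "first":
            out[i] = matrix.values[rows[0]]
        elif collision_policy == "mean":
            out[i] = matrix.values[rows].mean(axis=0)
        else:  # max_mean
            means = matrix.values[rows].mean(axis=1)
            out[i] = matrix.values[rows[int(np.argmax(means))]]
    return ExpressionMatrix(
        probe_ids=order,
        sample_ids=list(matrix.sample_ids),
        values=out,
        scale=matrix.scale,
    )
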
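"""Core domain containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allowed values for :attr:`ExpressionMatrix.scale`.
SCALES = ("linear_count", "log2_intensity", "log2_cpm", "standardized")


class TacitusError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TacitusError):
    """A file does not conform to the expected format."""


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TacitusError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A dense probes-by-samples real-valued matrix.

    Parameters
    ----------
    probe_ids : list of str
        Ordered row identifiers, unique.
    sample_ids : list of str
        Ordered column identifiers, unique.
    values : ndarray of shape (n_probes, n_samples)
        Expression values; no NaN/inf entries are allowed.
    scale : str
        Unit tag, one of :data:`SCALES`.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log2_intensity"

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.probe_ids), len(self.sample_ids))
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise TacitusError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if self.scale not in SCALES:
            raise TacitusError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise TacitusError("expression matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise TacitusError(f"unknown sample id: {sample_id!r}") from None

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Return a new matrix with columns restricted to ``sample_ids`` in order."""
        cols = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
            scale=self.scale,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and self.scale == other.scale
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


@dataclass
class SampleMetadata:
    """Per-sample attribute table.

    ``table`` maps sample id to a mapping attribute-name -> string value;
    every sample has an entry (possibly the empty string) for every
    attribute.
    """

    sample_ids: list[str]
    attributes: list[str]
    table: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.attributes = [str(a) for a in self.attributes]
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.attributes, "attribute name")
        norm: dict[str, dict[str, str]] = {}
        for sid in self.sample_ids:
            row = self.table.get(sid, {})
            norm[sid] = {a: str(row.get(a, "")) for a in self.attributes}
        self.table = norm

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def value(self, sample_id: str, attribute: str) -> str:
        return self.table[sample_id][attribute]

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.table]
        if missing:
            raise TacitusError(f"unknown sample ids: {missing}")
        return SampleMetadata(
            sample_ids=list(sample_ids),
            attributes=list(self.attributes),
            table={s: dict(self.table[s]) for s in sample_ids},
        )


@dataclass
class PlatformAnnotation:
    """Probe-to-identifier mappings for one platform.

    ``mapping`` maps probe id to a mapping namespace -> identifier (or
    ``None`` when the probe has no identifier in that namespace).
    """

    platform_id: str
    probe_ids: list[str]
    namespaces: list[str]
    mapping: dict[str, dict[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        _check_unique(self.probe_ids, "probe id")
        ns = set(self.namespaces)
        for probe, entry in self.mapping.items():
            extra = set(entry) - ns
            if extra:
                raise TacitusError(
                    f"probe {probe!r} maps namespaces {sorted(extra)} "
                    f"not declared in {self.namespaces}"
                )
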
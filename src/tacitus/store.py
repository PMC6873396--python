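"""File-backed dataset repository with indexes and streaming selection.

Layout: one directory per accession under the store root, holding

* ``matrix.tsv`` / ``metadata.tsv`` — export-dialect TSV files;
* ``sample_index.json`` — sample id -> 0-based column position;
* ``metadata_index.json`` — ordered attribute name list;
* ``fulltext_index.json`` — per attribute, token -> sorted sample id list;
* ``descriptor.json`` — accession, source, platform, visibility, counts;
* ``annotation.tsv`` — optional platform annotation pass-through copy;
* ``selections/<name>/`` — extracted matrix + metadata per selection.

Everything is plain TSV/JSON so a store can be inspected and diffed with
standard tools. Selection streams the stored matrix one probe-row at a
time, so peak memory is bounded by a single row plus the indexes.
"""

from __future__ import annotations

import json
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from tacitus import io_formats
from tacitus.types import ExpressionMatrix, SampleMetadata, TacitusError

_TOKEN_RE = re.compile(r"[^0-9a-zA-Z]+")

SOURCES = ("geo", "arrayexpress", "custom")
VISIBILITIES = ("public", "private")


def tokenize(text: str) -> list[str]:
    """Split on non-alphanumeric characters and lowercase; no stemming."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


@dataclass
class DatasetDescriptor:
    accession: str
    source: str = "custom"
    platform_id: str | None = None
    visibility: str = "public"
    n_probes: int = 0
    n_samples: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise TacitusError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.visibility not in VISIBILITIES:
            raise TacitusError(
                f"unknown visibility {self.visibility!r}; expected one of {VISIBILITIES}"
            )


@dataclass
class Selection:
    name: str
    accession: str
    sample_ids: list[str]
    matrix_path: str
    metadata_path: str


def build_fulltext_index(metadata: SampleMetadata) -> dict[str, dict[str, list[str]]]:
    """Inverted index: attribute -> token -> sorted list of sample ids."""
    index: dict[str, dict[str, set[str]]] = {a: {} for a in metadata.attributes}
    for sid in metadata.sample_ids:
        for attr in metadata.attributes:
            for token in tokenize(metadata.value(sid, attr)):
                index[attr].setdefault(token, set()).add(sid)
    return {
        attr: {tok: sorted(ids) for tok, ids in sorted(tokens.items())}
        for attr, tokens in index.items()
    }


class DatasetStore:
    """A directory of imported datasets addressable by accession."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    # -- paths ------------------------------------------------------------

    def dataset_dir(self, accession: str) -> Path:
        if not accession or "/" in accession or accession.startswith("."):
            raise TacitusError(f"invalid accession {accession!r}")
        return self.root / accession

    def list_accessions(self) -> list[str]:
        return sorted(
            p.name for p in self.root.iterdir() if (p / "descriptor.json").exists()
        )

    # -- import -----------------------------------------------------------

    def import_dataset(
        self,
        matrix: ExpressionMatrix,
        metadata: SampleMetadata,
        accession: str,
        source: str = "custom",
        platform_id: str | None = None,
        visibility: str = "public",
        annotation_path: str | Path | None = None,
        overwrite: bool = False,
    ) -> DatasetDescriptor:
        """Persist a dataset and build its indexes.

        The matrix and metadata must describe the same sample set; matrix
        column order defines the sample index positions.
        """
        mat_ids = set(matrix.sample_ids)
        meta_ids = set(metadata.sample_ids)
        if mat_ids != meta_ids:
            diff = sorted(mat_ids.symmetric_difference(meta_ids))
            raise TacitusError(
                f"matrix and metadata sample ids differ; symmetric difference: {diff}"
            )
        target = self.dataset_dir(accession)
        if target.exists():
            if not overwrite:
                raise TacitusError(
                    f"accession {accession!r} already exists (pass overwrite=True to replace)"
                )
            shutil.rmtree(target)
        target.mkdir(parents=True)

        # metadata rows stored in matrix column order for determinism
        metadata = metadata.subset(matrix.sample_ids)

        io_formats.write_table(matrix, target / "matrix.tsv", dialect="tsv")
        io_formats.write_metadata(metadata, target / "metadata.tsv", dialect="tsv")

        sample_index = {sid: i for i, sid in enumerate(matrix.sample_ids)}
        _dump_json(target / "sample_index.json", sample_index)
        _dump_json(target / "metadata_index.json", metadata.attributes)
        _dump_json(target / "fulltext_index.json", build_fulltext_index(metadata))

        paths = {
            "matrix": str(target / "matrix.tsv"),
            "metadata": str(target / "metadata.tsv"),
            "sample_index": str(target / "sample_index.json"),
            "metadata_index": str(target / "metadata_index.json"),
            "fulltext_index": str(target / "fulltext_index.json"),
        }
        if annotation_path is not None:
            shutil.copyfile(annotation_path, target / "annotation.tsv")
            paths["annotation"] = str(target / "annotation.tsv")
        descriptor = DatasetDescriptor(
            accession=accession,
            source=source,
            platform_id=platform_id,
            visibility=visibility,
            n_probes=matrix.n_probes,
            n_samples=matrix.n_samples,
            paths=paths,
        )
        _dump_json(
            target / "descriptor.json",
            {
                "accession": descriptor.accession,
                "source": descriptor.source,
                "platform_id": descriptor.platform_id,
                "visibility": descriptor.visibility,
                "n_probes": descriptor.n_probes,
                "n_samples": descriptor.n_samples,
                "paths": descriptor.paths,
            },
        )
        return descriptor

    def load_descriptor(self, accession: str) -> DatasetDescriptor:
        path = self.dataset_dir(accession) / "descriptor.json"
        if not path.exists():
            raise TacitusError(
                f"unknown accession {accession!r}; available: {self.list_accessions()}"
            )
        raw = json.loads(path.read_text(encoding="utf-8"))
        return DatasetDescriptor(**raw)

    def load_matrix(self, accession: str, scale: str = "log2_intensity") -> ExpressionMatrix:
        desc = self.load_descriptor(accession)
        return io_formats.read_table(desc.paths["matrix"], dialect="tsv", scale=scale)

    def load_metadata(self, accession: str) -> SampleMetadata:
        desc = self.load_descriptor(accession)
        return io_formats.read_metadata(desc.paths["metadata"], dialect="tsv")

    def load_sample_index(self, accession: str) -> dict[str, int]:
        desc = self.load_descriptor(accession)
        return json.loads(Path(desc.paths["sample_index"]).read_text(encoding="utf-8"))

    def load_metadata_index(self, accession: str) -> list[str]:
        desc = self.load_descriptor(accession)
        return json.loads(Path(desc.paths["metadata_index"]).read_text(encoding="utf-8"))

    def load_fulltext_index(self, accession: str) -> dict[str, dict[str, list[str]]]:
        desc = self.load_descriptor(accession)
        return json.loads(Path(desc.paths["fulltext_index"]).read_text(encoding="utf-8"))

    # -- search -----------------------------------------------------------

    def search_samples(
        self, accession: str, query: str, attribute: str | None = None
    ) -> set[str]:
        """Samples whose (tokenized) value for ``attribute`` — or any
        attribute when ``None`` — contains every query token. Case-insensitive."""
        index = self.load_fulltext_index(accession)
        if attribute is not None and attribute not in index:
            raise TacitusError(
                f"unknown attribute {attribute!r}; available: {list(index)}"
            )
        tokens = tokenize(query)
        if not tokens:
            return set()
        result: set[str] | None = None
        for token in tokens:
            if attribute is not None:
                hits = set(index[attribute].get(token, ()))
            else:
                hits = set()
                for tokens_map in index.values():
                    hits.update(tokens_map.get(token, ()))
            result = hits if result is None else (result & hits)
            if not result:
                return set()
        assert result is not None
        return result

    # -- selection --------------------------------------------------------

    def iter_matrix_rows(self, accession: str) -> Iterator[tuple[str, list[str]]]:
        """Yield (probe_id, raw value fields) one stored matrix row at a time."""
        desc = self.load_descriptor(accession)
        with open(desc.paths["matrix"], "r", encoding="utf-8", newline="") as fh:
            next(fh)  # header
            for line in fh:
                line = line.rstrip("\r\n")
                if not line:
                    continue
                fields = line.split("\t")
                yield fields[0], fields[1:]

    def select_samples(
        self, accession: str, sample_ids: list[str], name: str
    ) -> Selection:
        """Extract the requested columns, streaming one probe-row at a time.

        The extracted matrix has the requested columns in request order; the
        metadata subset follows. Output files obey the export dialect.
        """
        if not sample_ids:
            raise TacitusError("empty sample id list")
        if len(set(sample_ids)) != len(sample_ids):
            raise TacitusError("duplicate sample ids in selection")
        sample_index = self.load_sample_index(accession)
        for sid in sample_ids:
            if sid not in sample_index:
                raise TacitusError(f"unknown sample id: {sid!r}")
        positions = [sample_index[sid] for sid in sample_ids]

        sel_dir = self.dataset_dir(accession) / "selections" / name
        sel_dir.mkdir(parents=True, exist_ok=True)
        matrix_path = sel_dir / "matrix.tsv"
        metadata_path = sel_dir / "metadata.tsv"

        with open(matrix_path, "w", encoding="utf-8", newline="") as out:
            out.write("\t" + "\t".join(sample_ids) + "\n")
            for probe, fields in self.iter_matrix_rows(accession):
                out.write("\t".join([probe] + [fields[p] for p in positions]) + "\n")

        metadata = self.load_metadata(accession).subset(sample_ids)
        io_formats.write_metadata(metadata, metadata_path, dialect="tsv")

        selection = Selection(
            name=name,
            accession=accession,
            sample_ids=list(sample_ids),
            matrix_path=str(matrix_path),
            metadata_path=str(metadata_path),
        )
        _dump_json(
            sel_dir / "selection.json",
            {
                "name": name,
                "accession": accession,
                "sample_ids": list(sample_ids),
                "matrix_path": str(matrix_path),
                "metadata_path": str(metadata_path),
            },
        )
        return selection

    def load_selection(self, accession: str, name: str) -> Selection:
        path = self.dataset_dir(accession) / "selections" / name / "selection.json"
        if not path.exists():
            raise TacitusError(f"unknown selection {name!r} for accession {accession!r}")
        return Selection(**json.loads(path.read_text(encoding="utf-8")))


def _dump_json(path: Path, obj: object) -> None:
    path.write_text(
        json.dumps(obj, indent=1, sort_keys=False, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
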
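"""Readers, writers and merge logic for KEGG Orthology (KO) annotation tables.

Non-model organisms are annotated by mapping predicted proteins to KO
ortholog groups with tools such as eggNOG-mapper, BlastKOALA or KAAS.  This
module parses those annotator outputs into a single canonical structure,
:class:`AnnotationMap` (gene id -> set of KO accessions), merges up to three
sources by union ("sum of annotations") or intersection ("minimum"), and
round-trips the canonical headerless two-column ``gene<TAB>KO`` table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationMap",
    "AnnotationFormatError",
    "normalize_ko",
    "parse_eggnog",
    "parse_two_column",
    "merge_annotations",
    "write_annotation_table",
    "read_annotation_table",
]

_KO_RE = re.compile(r"^K\d{5}$")


class AnnotationFormatError(ValueError):
    """A file does not follow the expected annotator dialect."""


def normalize_ko(token: str, *, context: str = "") -> str:
    """Normalize a KO token: strip an optional ``ko:`` prefix, upper-case.

    Anything that does not match ``K`` + 5 digits afterwards is a hard
    format error -- failing fast beats silently losing annotations.
    """
    ko = token.strip()
    if ko.lower().startswith("ko:"):
        ko = ko[3:]
    ko = ko.upper()
    if not _KO_RE.match(ko):
        where = f" ({context})" if context else ""
        raise AnnotationFormatError(
            f"malformed KO accession {token!r}{where}: expected 'K' + 5 digits"
        )
    return ko


@dataclass
class AnnotationMap:
    """Gene -> set-of-KO mapping plus the labels of contributing annotators.

    Invariants: no gene maps to an empty KO set (such genes are simply
    absent), every KO matches ``K\\d{5}``, and gene ids are unique keys.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    source_labels: list[str] = field(default_factory=list)

    def add(self, gene_id: str, kos: Iterable[str]) -> None:
        """Merge *kos* (already normalized) into the entry for *gene_id*."""
        kos = set(kos)
        if not gene_id:
            raise AnnotationFormatError("empty gene id")
        if not kos:
            return
        self.entries.setdefault(gene_id, set()).update(kos)

    def pairs(self) -> set[tuple[str, str]]:
        """All (gene, KO) pairs as a flat set."""
        return {(g, k) for g, kos in self.entries.items() for k in kos}

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], source_labels: Sequence[str] = ()
    ) -> "AnnotationMap":
        amap = cls(source_labels=list(source_labels))
        for gene, ko in pairs:
            amap.add(gene, [ko])
        return amap

    @property
    def n_genes(self) -> int:
        return len(self.entries)

    @property
    def n_pairs(self) -> int:
        return sum(len(kos) for kos in self.entries.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __getitem__(self, gene_id: str) -> set[str]:
        return self.entries[gene_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self.entries == other.entries


def parse_eggnog(path: str | Path) -> AnnotationMap:
    """Parse an eggNOG-mapper v2-style ``.emapper.annotations`` table.

    Lines starting ``##`` are comments, the header line starts ``#query``,
    and the KO column is located by its header name ``KEGG_ko`` (never by
    position).  Cells are ``-`` for missing or comma-separated ``ko:Kxxxxx``
    tokens.
    """
    path = Path(path)
    amap = AnnotationMap(source_labels=["eggnog"])
    ko_col: int | None = None
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise OSError(f"cannot read eggNOG annotations {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#"):
            header = [h.strip() for h in line.lstrip("#").split("\t")]
            if "KEGG_ko" not in header:
                raise AnnotationFormatError(
                    f"{path}: header has no 'KEGG_ko' column "
                    "(is this an eggNOG-mapper annotations file?)"
                )
            ko_col = header.index("KEGG_ko")
            continue
        if ko_col is None:
            raise AnnotationFormatError(
                f"{path}:{lineno}: data row before the '#query' header line"
            )
        fields = line.split("\t")
        if len(fields) <= ko_col:
            raise AnnotationFormatError(
                f"{path}:{lineno}: row has {len(fields)} fields, "
                f"KEGG_ko expected at column {ko_col + 1}"
            )
        gene = fields[0].strip()
        cell = fields[ko_col].strip()
        if cell in ("-", ""):
            continue
        kos = [
            normalize_ko(tok, context=f"{path}:{lineno}")
            for tok in cell.split(",")
            if tok.strip()
        ]
        amap.add(gene, kos)
    return amap


def parse_two_column(path: str | Path) -> AnnotationMap:
    """Parse a two-column ``gene<TAB>KO`` table (BlastKOALA / KAAS exports).

    Rows with an empty KO cell are skipped (the annotator found no
    ortholog); repeated gene ids accumulate KOs by union.
    """
    path = Path(path)
    amap = AnnotationMap(source_labels=["two_column"])
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise OSError(f"cannot read annotation table {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise AnnotationFormatError(
                f"{path}:{lineno}: expected two tab-separated columns, "
                f"got {line!r}"
            )
        fields = line.split("\t")
        gene = fields[0].strip()
        ko_cell = fields[1].strip()
        if not gene:
            raise AnnotationFormatError(f"{path}:{lineno}: empty gene id")
        if not ko_cell:
            continue
        amap.add(gene, [normalize_ko(ko_cell, context=f"{path}:{lineno}")])
    return amap


def merge_annotations(
    maps: Sequence[AnnotationMap], mode: str = "union"
) -> AnnotationMap:
    """Merge 1-3 annotation maps by ``union`` or ``intersection``.

    Union keeps every (gene, KO) pair present in any input; intersection
    keeps pairs present in every input.  Genes left with no KOs are dropped.
    A single input is returned unchanged under either mode.
    """
    if not 1 <= len(maps) <= 3:
        raise ValueError(
            f"expected between 1 and 3 annotation maps, got {len(maps)}"
        )
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode {mode!r}")
    labels = [lab for m in maps for lab in m.source_labels]
    if len(maps) == 1:
        return AnnotationMap(
            entries={g: set(k) for g, k in maps[0].entries.items()},
            source_labels=labels,
        )
    pair_sets = [m.pairs() for m in maps]
    if mode == "union":
        pairs = set.union(*pair_sets)
    else:
        pairs = set.intersection(*pair_sets)
    return AnnotationMap.from_pairs(pairs, source_labels=labels)


def write_annotation_table(amap: AnnotationMap, path: str | Path) -> int:
    """Write the canonical two-column table; returns the row count.

    One ``gene<TAB>KO`` row per pair, genes sorted lexicographically then
    KOs sorted, so the output is byte-deterministic.
    """
    path = Path(path)
    rows = 0
    try:
        with path.open("w", encoding="utf-8") as fh:
            for gene in sorted(amap.entries):
                for ko in sorted(amap.entries[gene]):
                    fh.write(f"{gene}\t{ko}\n")
                    rows += 1
    except OSError as exc:
        raise OSError(f"cannot write annotation table {path}: {exc}") from exc
    return rows


def read_annotation_table(path: str | Path) -> AnnotationMap:
    """Read a canonical two-column table; inverse of ``write_annotation_table``."""
    return parse_two_column(path)
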
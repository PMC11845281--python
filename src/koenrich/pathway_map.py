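"""KO -> pathway catalog and the pathway -> gene ("term2gene") mapping.

The catalog is a plain offline three-column table
``ko_id<TAB>pathway_id<TAB>pathway_name`` that stands in for live KEGG
access, so the whole pipeline runs without a network connection.  The
term2gene map links each pathway to the genes that carry at least one of
its KOs, keeping per-link provenance (which KOs justified the link) for
pathway-diagram highlighting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .annotation_io import AnnotationMap, normalize_ko

__all__ = [
    "Pathway",
    "PathwayCatalog",
    "Term2Gene",
    "CatalogError",
    "normalize_pathway_id",
    "load_catalog",
    "write_catalog",
    "build_term2gene",
]

_PATHWAY_RE = re.compile(r"^ko\d{5}$")


class CatalogError(ValueError):
    """Malformed or internally inconsistent pathway catalog."""


def normalize_pathway_id(token: str, *, context: str = "") -> str:
    """Normalize ``path:ko00010`` / ``map00010`` / ``ko00010`` to ``ko00010``."""
    pid = token.strip()
    if pid.lower().startswith("path:"):
        pid = pid[5:]
    pid = pid.lower()
    if pid.startswith("map"):
        pid = "ko" + pid[3:]
    if not _PATHWAY_RE.match(pid):
        where = f" ({context})" if context else ""
        raise CatalogError(
            f"malformed pathway id {token!r}{where}: expected 'ko' + 5 digits"
        )
    return pid


@dataclass
class Pathway:
    name: str
    kos: set[str] = field(default_factory=set)


@dataclass
class PathwayCatalog:
    """pathway_id -> (display name, set of member KOs)."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def add(self, pathway_id: str, name: str, kos: Iterable[str]) -> None:
        pid = normalize_pathway_id(pathway_id)
        name = name.strip()
        if not name:
            raise CatalogError(f"pathway {pid} has an empty name")
        entry = self.pathways.get(pid)
        if entry is None:
            self.pathways[pid] = Pathway(name=name, kos=set(kos))
        else:
            if entry.name != name:
                raise CatalogError(
                    f"pathway {pid} has conflicting names: "
                    f"{entry.name!r} vs {name!r}"
                )
            entry.kos.update(kos)

    def ko_index(self) -> dict[str, set[str]]:
        """Inverted index KO -> set of pathway ids."""
        index: dict[str, set[str]] = {}
        for pid, pw in self.pathways.items():
            for ko in pw.kos:
                index.setdefault(ko, set()).add(pid)
        return index

    def names(self) -> dict[str, str]:
        return {pid: pw.name for pid, pw in self.pathways.items()}

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.pathways

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]


def load_catalog(path: str | Path) -> PathwayCatalog:
    """Load a 3-column ``ko<TAB>pathway<TAB>name`` catalog file.

    Pathway ids are normalized; the same pathway id appearing with two
    different names is a consistency error.
    """
    path = Path(path)
    catalog = PathwayCatalog()
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise OSError(f"cannot read pathway catalog {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise CatalogError(
                f"{path}:{lineno}: expected 3 tab-separated columns "
                f"(ko, pathway, name), got {len(fields)}"
            )
        ko = normalize_ko(fields[0], context=f"{path}:{lineno}")
        pid = normalize_pathway_id(fields[1], context=f"{path}:{lineno}")
        name = fields[2].strip()
        if not name:
            raise CatalogError(f"{path}:{lineno}: empty pathway name")
        catalog.add(pid, name, [ko])
    return catalog


def write_catalog(catalog: PathwayCatalog, path: str | Path) -> int:
    """Write a catalog back to the 3-column format; returns the row count."""
    path = Path(path)
    rows = 0
    with path.open("w", encoding="utf-8") as fh:
        for pid in sorted(catalog.pathways):
            pw = catalog.pathways[pid]
            for ko in sorted(pw.kos):
                fh.write(f"{ko}\t{pid}\t{pw.name}\n")
                rows += 1
    return rows


@dataclass
class Term2Gene:
    """pathway_id -> gene set, with (pathway, gene) -> witnessing-KO provenance.

    A gene appears under a pathway iff it carries at least one KO of that
    pathway's KO set; pathways with zero annotated genes are absent.
    """

    terms: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        """All genes annotated to at least one pathway."""
        return {g for members in self.terms.values() for g in members}

    def __len__(self) -> int:
        return len(self.terms)


def build_term2gene(
    annotation: AnnotationMap, catalog: PathwayCatalog
) -> Term2Gene:
    """Link genes to pathways through shared KOs.

    Gene-level semantics: a gene is listed once under a pathway no matter
    how many of its KOs belong to it; all witnessing KOs are kept in the
    provenance map (KO-level detail is only needed when painting pathway
    diagrams).
    """
    index = catalog.ko_index()
    t2g = Term2Gene()
    for gene, kos in annotation.entries.items():
        for ko in kos:
            for pid in index.get(ko, ()):
                t2g.terms.setdefault(pid, set()).add(gene)
                t2g.provenance.setdefault((pid, gene), set()).add(ko)
    return t2g
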
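"""Shared fixtures: tiny catalogs, annotations, and a toy KGML diagram.

All fixtures are generated programmatically; nothing is stored on disk.
"""

from __future__ import annotations

import textwrap

import pytest

from koenrich.annotation_io import AnnotationMap
from koenrich.enrichment import make_query, run_enrichment
from koenrich.pathway_map import PathwayCatalog, build_term2gene


@pytest.fixture
def small_catalog() -> PathwayCatalog:
    """Three pathways over six KOs, with one shared KO (K00003)."""
    cat = PathwayCatalog()
    cat.add("ko00010", "Glycolysis", {"K00001", "K00002", "K00003"})
    cat.add("ko00020", "TCA cycle", {"K00003", "K00004"})
    cat.add("ko00030", "Pentose phosphate", {"K00005", "K00006"})
    return cat


@pytest.fixture
def small_annotation() -> AnnotationMap:
    """Eight genes; g7 carries an unmapped KO, g8 is unannotated via K99999."""
    entries = {
        "g1": {"K00001"},
        "g2": {"K00002", "K00003"},
        "g3": {"K00003"},
        "g4": {"K00004"},
        "g5": {"K00005"},
        "g6": {"K00006"},
        "g7": {"K99999"},
    }
    return AnnotationMap(entries={g: set(k) for g, k in entries.items()})


@pytest.fixture
def small_table(small_annotation, small_catalog):
    """Enrichment table for a 3-gene foreground over the 6-gene universe."""
    t2g = build_term2gene(small_annotation, small_catalog)
    query = make_query(
        ["g1", "g2", "g3"], [f"g{i}" for i in range(1, 8)], t2g
    )
    return run_enrichment(query, t2g, small_catalog)


@pytest.fixture
def toy_kgml(tmp_path):
    """KGML file with 3 ortholog entries; KOs K00001/K00002 on two of them."""
    xml = textwrap.dedent(
        """\
        <?xml version="1.0"?>
        <pathway name="path:ko00010" org="ko" number="00010" title="Toy pathway">
          <entry id="1" name="ko:K00001 ko:K00009" type="ortholog">
            <graphics name="E1" x="100" y="50" width="46" height="17" type="rectangle"/>
          </entry>
          <entry id="2" name="ko:K00002" type="ortholog">
            <graphics name="E2" x="200" y="120" width="46" height="17" type="rectangle"/>
          </entry>
          <entry id="3" name="ko:K00777" type="ortholog">
            <graphics name="E3" x="300" y="200" width="46" height="17" type="rectangle"/>
          </entry>
        </pathway>
        """
    )
    path = tmp_path / "ko00010.xml"
    path.write_text(xml, encoding="utf-8")
    return path
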
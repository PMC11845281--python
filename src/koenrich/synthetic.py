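"""Seeded synthetic catalogs, annotations and gene lists with spike-ins.

The generator emulates a draft-genome KO annotation: a catalog of synthetic
pathways drawn from a shared KO pool (so pathways overlap, as KEGG maps
do), genes carrying a handful of KOs each, a fraction of KOs mapping to no
pathway (orthologs without a pathway assignment), and a foreground list
that either is a uniform sample (null design) or preferentially samples
members of designated "spiked" pathways.  Everything is fully determined
by the design's seed, and a truth manifest records the spiked pathways
with their realized contingency counts so downstream checks never have to
re-derive ground truth from generator internals.

Defaults mirror a published demo at draft-genome scale: 12 134 background
genes with a 437-gene foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation_io import AnnotationMap, write_annotation_table
from .enrichment import make_query
from .pathway_map import PathwayCatalog, Term2Gene, build_term2gene, write_catalog

__all__ = ["SpikeDesign", "SyntheticDataset", "generate_dataset", "generate_fixture"]

# Shared-KO-pool geometry: pathways draw from a pool sized at 80% of the
# summed pathway sizes (moderate overlap between pathways); a further 30%
# of the pool is KOs that belong to no pathway, so some annotated genes
# fall outside the test universe, as happens with real draft annotations.
_POOL_OVERLAP = 0.8
_UNMAPPED_FRACTION = 0.3


@dataclass(frozen=True)
class SpikeDesign:
    """Parameters of one synthetic study.

    ``spike_fraction`` is the fraction of the foreground drawn from the
    spiked pathways' member genes; 0 gives a null (uniform) foreground.
    """

    n_genes: int = 12134
    n_pathways: int = 150
    kos_per_pathway: tuple[int, int] = (10, 60)
    kos_per_gene: tuple[int, int] = (1, 3)
    fg_size: int = 437
    spiked_pathway_count: int = 2
    spike_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fg_size > self.n_genes:
            raise ValueError("fg_size cannot exceed n_genes")
        if self.spiked_pathway_count > self.n_pathways:
            raise ValueError("spiked_pathway_count cannot exceed n_pathways")
        if not 0 <= self.spike_fraction <= 1:
            raise ValueError("spike_fraction must lie in [0, 1]")
        for lo, hi in (self.kos_per_pathway, self.kos_per_gene):
            if not 1 <= lo <= hi:
                raise ValueError("KO count ranges must satisfy 1 <= lo <= hi")


@dataclass
class SyntheticDataset:
    catalog: PathwayCatalog
    annotation: AnnotationMap
    foreground: list[str]
    background: list[str]
    t2g: Term2Gene
    truth: list[dict] = field(default_factory=list)


def _ko_id(i: int) -> str:
    return f"K{i + 1:05d}"


def _gene_id(i: int) -> str:
    return f"g{i + 1:06d}"


def _pathway_id(i: int) -> str:
    return f"ko{(i + 1) * 10:05d}"


def generate_dataset(design: SpikeDesign) -> SyntheticDataset:
    """Generate one in-memory study; deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)

    lo, hi = design.kos_per_pathway
    sizes = rng.integers(lo, hi + 1, size=design.n_pathways)
    pool_mapped = max(int(round(_POOL_OVERLAP * int(sizes.sum()))), int(sizes.max()))
    pool_total = pool_mapped + int(round(_UNMAPPED_FRACTION * pool_mapped))
    if pool_total > 99999:
        raise ValueError("design requires more than 99999 distinct KOs")

    catalog = PathwayCatalog()
    for i in range(design.n_pathways):
        kos = rng.choice(pool_mapped, size=int(sizes[i]), replace=False)
        catalog.add(
            _pathway_id(i),
            f"Synthetic pathway {i + 1:03d}",
            {_ko_id(int(j)) for j in kos},
        )

    glo, ghi = design.kos_per_gene
    counts = rng.integers(glo, ghi + 1, size=design.n_genes)
    draws = rng.integers(0, pool_total, size=int(counts.sum()))
    annotation = AnnotationMap(source_labels=["synthetic"])
    offset = 0
    for i in range(design.n_genes):
        c = int(counts[i])
        kos = {_ko_id(int(j)) for j in draws[offset : offset + c]}
        offset += c
        annotation.add(_gene_id(i), kos)

    t2g = build_term2gene(annotation, catalog)
    background = [_gene_id(i) for i in range(design.n_genes)]

    truth: list[dict] = []
    if design.spike_fraction == 0 or design.spiked_pathway_count == 0:
        fg = sorted(
            rng.choice(background, size=design.fg_size, replace=False).tolist()
        )
    else:
        spiked_idx = rng.choice(
            design.n_pathways, size=design.spiked_pathway_count, replace=False
        )
        spiked_ids = sorted(_pathway_id(int(i)) for i in spiked_idx)
        members = sorted(
            {g for pid in spiked_ids for g in t2g.terms.get(pid, set())}
        )
        n_spike = int(round(design.spike_fraction * design.fg_size))
        if n_spike > len(members):
            raise ValueError(
                f"infeasible design: spike needs {n_spike} genes but the "
                f"spiked pathway(s) only cover {len(members)}"
            )
        spike_genes = rng.choice(members, size=n_spike, replace=False).tolist()
        rest_pool = sorted(set(background) - set(spike_genes))
        rest = rng.choice(
            rest_pool, size=design.fg_size - n_spike, replace=False
        ).tolist()
        fg = sorted(spike_genes + rest)

        query = make_query(fg, background, t2g)
        N = len(query.universe)
        n = len(query.effective_foreground)
        for pid in spiked_ids:
            universe_members = t2g.terms.get(pid, set()) & query.universe
            truth.append(
                {
                    "pathway_id": pid,
                    "pathway_name": catalog[pid].name,
                    "k": len(universe_members & query.effective_foreground),
                    "n": n,
                    "K": len(universe_members),
                    "N": N,
                }
            )

    return SyntheticDataset(
        catalog=catalog,
        annotation=annotation,
        foreground=fg,
        background=background,
        t2g=t2g,
        truth=truth,
    )


def generate_fixture(design: SpikeDesign, outdir: str | Path) -> dict[str, Path]:
    """Generate a study and write it in the formats the pipeline consumes.

    Emits ``catalog.tsv`` (3-column KO/pathway/name), ``annotation.tsv``
    (2-column gene/KO), ``foreground.txt`` / ``background.txt`` (one gene
    per line) and ``truth.tsv`` (spiked pathways with realized k, n, K, N).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(design)
    paths = {
        "catalog": outdir / "catalog.tsv",
        "annotation": outdir / "annotation.tsv",
        "foreground": outdir / "foreground.txt",
        "background": outdir / "background.txt",
        "truth": outdir / "truth.tsv",
    }
    write_catalog(ds.catalog, paths["catalog"])
    write_annotation_table(ds.annotation, paths["annotation"])
    paths["foreground"].write_text("\n".join(ds.foreground) + "\n", encoding="utf-8")
    paths["background"].write_text("\n".join(ds.background) + "\n", encoding="utf-8")
    with paths["truth"].open("w", encoding="utf-8") as fh:
        fh.write("pathway_id\tpathway_name\tk\tn\tK\tN\n")
        for row in ds.truth:
            fh.write(
                f"{row['pathway_id']}\t{row['pathway_name']}\t"
                f"{row['k']}\t{row['n']}\t{row['K']}\t{row['N']}\n"
            )
    return paths
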
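"""Over-representation statistics: hypergeometric tail, fold enrichment, BH.

The test asks, for each KEGG pathway, whether the foreground gene list
contains more pathway members than expected when drawing ``n`` genes
without replacement from a universe of ``N`` annotated background genes of
which ``K`` belong to the pathway.  The p-value is the upper tail
``P(X >= k)`` of ``Hypergeometric(N, K, n)`` -- the same number as a
one-sided (greater) Fisher exact test on the corresponding 2x2 table.
Multiple testing across pathways is corrected with the Benjamini-Hochberg
step-up procedure.

Universe convention: the universe is the subset of background genes that
are annotated to at least one pathway (unannotated genes carry no
information for a pathway-membership draw).  This changes ``N`` relative
to the raw background size, so the dropped-gene counts are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .pathway_map import PathwayCatalog, Term2Gene

__all__ = [
    "GeneSetQuery",
    "ContingencyCounts",
    "EnrichmentRecord",
    "EnrichmentTable",
    "make_query",
    "hypergeom_pvalue",
    "fold_enrichment",
    "bh_adjust",
    "run_enrichment",
    "filter_significant",
    "write_results",
    "read_results",
    "read_gene_list",
]

logger = logging.getLogger("koenrich")


@dataclass(frozen=True)
class GeneSetQuery:
    """Foreground/background gene sets and the derived annotated universe.

    ``universe`` is background ∩ annotated-to-≥1-pathway;
    ``effective_foreground`` is foreground ∩ universe.  Counts of dropped
    foreground genes (absent from background, or unannotated) are recorded.
    """

    foreground: frozenset[str]
    background: frozenset[str]
    universe: frozenset[str]
    effective_foreground: frozenset[str]
    n_fg_not_in_background: int = 0
    n_fg_unannotated: int = 0
    n_bg_unannotated: int = 0


def make_query(
    foreground: Iterable[str],
    background: Iterable[str],
    t2g: Term2Gene,
) -> GeneSetQuery:
    """Derive the test universe from raw gene lists and the term2gene map.

    Raises if no foreground gene survives (nothing to test); foreground
    genes outside the background are dropped with a warning, not an error.
    """
    fg = frozenset(g.strip() for g in foreground if g.strip())
    bg = frozenset(g.strip() for g in background if g.strip())
    if not fg or not bg:
        raise ValueError("foreground and background lists must be non-empty")
    annotated = t2g.genes()
    universe = frozenset(bg & annotated)
    fg_in_bg = fg & bg
    eff_fg = frozenset(fg_in_bg & universe)
    n_outside = len(fg) - len(fg_in_bg)
    n_unann = len(fg_in_bg) - len(eff_fg)
    if n_outside:
        logger.warning(
            "%d foreground gene(s) absent from the background were dropped",
            n_outside,
        )
    if n_unann:
        logger.warning(
            "%d foreground gene(s) with no pathway annotation were dropped",
            n_unann,
        )
    if not eff_fg:
        raise ValueError(
            "no annotated foreground genes: every foreground gene is either "
            "absent from the background or maps to no pathway"
        )
    return GeneSetQuery(
        foreground=fg,
        background=bg,
        universe=universe,
        effective_foreground=eff_fg,
        n_fg_not_in_background=n_outside,
        n_fg_unannotated=n_unann,
        n_bg_unannotated=len(bg) - len(universe),
    )


@dataclass(frozen=True)
class ContingencyCounts:
    """The four integers behind one pathway's 2x2 table.

    k: foreground genes in the pathway; n: effective foreground size;
    K: universe genes in the pathway; N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        k, n, K, N = self.k, self.n, self.K, self.N
        if not (0 <= n <= N and 0 <= K <= N):
            raise ValueError(f"invalid counts: n={n}, K={K} must lie in [0, N={N}]")
        if not (max(0, n + K - N) <= k <= min(n, K)):
            raise ValueError(
                f"invalid counts: k={k} outside "
                f"[{max(0, n + K - N)}, {min(n, K)}] for n={n}, K={K}, N={N}"
            )


def _log_comb(a: int, b: int) -> float:
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def hypergeom_pvalue(c: ContingencyCounts) -> float:
    """Upper-tail p-value ``P(X >= k)`` for X ~ Hypergeometric(N, K, n).

    Equivalent to R's ``phyper(k - 1, K, N - K, n, lower.tail = FALSE)``;
    the tail *includes* k.  Summed in log space with lgamma-based binomial
    coefficients so it stays stable at universe sizes around 1e4.
    """
    k, n, K, N = c.k, c.n, c.K, c.N
    if k == 0:
        return 1.0
    hi = min(n, K)
    denom = _log_comb(N, n)
    log_terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - denom
        for i in range(k, hi + 1)
    ]
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def fold_enrichment(c: ContingencyCounts) -> float:
    """Fold enrichment (k/n) / (K/N): foreground vs background pathway fraction."""
    if c.K == 0 or c.n == 0:
        raise ValueError(
            f"fold enrichment undefined for K={c.K}, n={c.n} (division by zero)"
        )
    return (c.k / c.n) / (c.K / c.N)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min(1, min_{j>=i} p_(j) * m / j)`` on the sorted vector;
    permutation-equivariant and elementwise >= the raw p-values.
    """
    pvals = list(pvalues)
    if not pvals:
        raise ValueError("empty p-value list")
    arr = np.asarray(pvals, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's row of the result table."""

    pathway_id: str
    pathway_name: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    p_adjusted: float
    genes: tuple[str, ...]

    @property
    def gene_ratio(self) -> tuple[int, int]:
        return (self.k, self.n)

    @property
    def bg_ratio(self) -> tuple[int, int]:
        return (self.K, self.N)


@dataclass
class EnrichmentTable:
    """Ranked result table, sorted by (p_adjusted, p_value, pathway_id)."""

    records: list[EnrichmentRecord] = field(default_factory=list)
    thresholds: dict[str, float] = field(
        default_factory=lambda: {"alpha_p": 0.05, "alpha_padj": 0.05}
    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pathway_id": [r.pathway_id for r in self.records],
                "pathway_name": [r.pathway_name for r in self.records],
                "gene_ratio": [f"{r.k}/{r.n}" for r in self.records],
                "bg_ratio": [f"{r.K}/{r.N}" for r in self.records],
                "fold_enrichment": [r.fold_enrichment for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "p_adjusted": [r.p_adjusted for r in self.records],
                "genes": [",".join(r.genes) for r in self.records],
            }
        )


def run_enrichment(
    query: GeneSetQuery,
    t2g: Term2Gene,
    catalog: PathwayCatalog | None = None,
    *,
    drop_empty: bool = False,
    alpha_p: float = 0.05,
    alpha_padj: float = 0.05,
) -> EnrichmentTable:
    """Test every pathway with >= 1 universe gene against the foreground.

    BH is applied across exactly the set of tested pathways.  Pathways
    with k = 0 are tested (p = 1) and kept unless ``drop_empty`` is set,
    which restricts the family to k >= 1 (and so changes m).  ``catalog``
    supplies display names; without it the pathway id doubles as the name.
    """
    if not query.universe:
        raise ValueError("empty universe: no annotated background genes")
    names = catalog.names() if catalog is not None else {}
    N = len(query.universe)
    n = len(query.effective_foreground)
    tested: list[tuple[str, ContingencyCounts, tuple[str, ...]]] = []
    for pid in sorted(t2g.terms):
        members = t2g.terms[pid] & query.universe
        K = len(members)
        if K == 0:
            continue
        fg_members = tuple(sorted(members & query.effective_foreground))
        k = len(fg_members)
        if drop_empty and k == 0:
            continue
        tested.append((pid, ContingencyCounts(k=k, n=n, K=K, N=N), fg_members))
    if not tested:
        return EnrichmentTable(
            records=[], thresholds={"alpha_p": alpha_p, "alpha_padj": alpha_padj}
        )
    pvals = [hypergeom_pvalue(c) for _, c, _ in tested]
    padj = bh_adjust(pvals)
    records = [
        EnrichmentRecord(
            pathway_id=pid,
            pathway_name=names.get(pid, pid),
            k=c.k,
            n=c.n,
            K=c.K,
            N=c.N,
            fold_enrichment=fold_enrichment(c),
            p_value=p,
            p_adjusted=q,
            genes=genes,
        )
        for (pid, c, genes), p, q in zip(tested, pvals, padj)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.p_value, r.pathway_id))
    return EnrichmentTable(
        records=records, thresholds={"alpha_p": alpha_p, "alpha_padj": alpha_padj}
    )


def filter_significant(
    table: EnrichmentTable, by: str = "padj", alpha: float = 0.05
) -> EnrichmentTable:
    """Keep records with the chosen statistic strictly below *alpha*.

    ``alpha = 1.0`` disables the filter entirely (vacuous threshold), so
    records with p exactly 1 are still retained in that case.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if by not in ("p", "padj"):
        raise ValueError(f"filter statistic must be 'p' or 'padj', got {by!r}")
    if alpha == 1.0:
        kept = list(table.records)
    else:
        stat = (lambda r: r.p_value) if by == "p" else (lambda r: r.p_adjusted)
        kept = [r for r in table.records if stat(r) < alpha]
    return EnrichmentTable(records=kept, thresholds=dict(table.thresholds))


_COLUMNS = (
    "pathway_id",
    "pathway_name",
    "gene_ratio",
    "bg_ratio",
    "fold_enrichment",
    "p_value",
    "p_adjusted",
    "genes",
)


def write_results(table: EnrichmentTable, path: str | Path) -> int:
    """Write the tab-delimited result table; returns the data row count.

    Ratios are printed as ``k/n`` and ``K/N``; reals with 9 significant
    digits.
    """
    path = Path(path)
    rows = 0
    try:
        with path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(_COLUMNS) + "\n")
            for r in table.records:
                fh.write(
                    "\t".join(
                        [
                            r.pathway_id,
                            r.pathway_name,
                            f"{r.k}/{r.n}",
                            f"{r.K}/{r.N}",
                            f"{r.fold_enrichment:.9g}",
                            f"{r.p_value:.9g}",
                            f"{r.p_adjusted:.9g}",
                            ",".join(r.genes),
                        ]
                    )
                    + "\n"
                )
                rows += 1
    except OSError as exc:
        raise OSError(f"cannot write results table {path}: {exc}") from exc
    return rows


def read_results(path: str | Path) -> EnrichmentTable:
    """Parse a table written by :func:`write_results` (to printed precision)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != list(_COLUMNS):
        raise ValueError(f"{path}: not a koenrich results table")
    records = []
    for line in lines[1:]:
        f = line.split("\t")
        k, n = (int(x) for x in f[2].split("/"))
        K, N = (int(x) for x in f[3].split("/"))
        records.append(
            EnrichmentRecord(
                pathway_id=f[0],
                pathway_name=f[1],
                k=k,
                n=n,
                K=K,
                N=N,
                fold_enrichment=float(f[4]),
                p_value=float(f[5]),
                p_adjusted=float(f[6]),
                genes=tuple(f[7].split(",")) if f[7] else (),
            )
        )
    return EnrichmentTable(records=records)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a newline-delimited gene list; ``#`` comment lines are skipped."""
    path = Path(path)
    genes = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes
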
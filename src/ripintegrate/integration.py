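"""Set-overlap integration of expression, splicing and binding, plus generic
GMT over-representation with BH-FDR.

The overlap statistic is the hypergeometric upper tail: drawing n genes
(set B) from a universe of N that contains K marked genes (set A), the
p-value is P[X >= x] for the observed intersection x.  The universe is a
required argument — in the pipeline it defaults to the genes detected in
the RNA-seq stage (non-zero count in at least one sample), which is the
dominant unstated parameter behind any overlap p-value of this kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OverlapResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float
    overlapped: tuple[str, ...] = ()


def hypergeom_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Hypergeometric upper-tail test of the overlap between two gene sets.

    Members outside the universe are dropped (with a count of 0 they cannot
    contribute); an empty universe is an error.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a = set(set_a) & uni
    b = set(set_b) & uni
    x = len(a & b)
    N, K, n = len(uni), len(a), len(b)
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return OverlapResult(N, K, n, x, p, tuple(sorted(a & b)))


@dataclass
class EnrichedTerm:
    term_id: str
    description: str
    term_size: int
    hits: int
    p_value: float
    fdr: float
    hit_genes: tuple[str, ...]


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Standard GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = (parts[1], {g for g in parts[2:] if g})
    return terms


def ora(
    genes: Iterable[str],
    gmt: Mapping[str, tuple[str, set[str]]],
    universe: Iterable[str],
    fdr_threshold: float = 0.05,
) -> list[EnrichedTerm]:
    """Over-representation of a query gene list in each GMT term.

    One hypergeometric upper-tail test per term (term genes restricted to
    the universe), BH-FDR across terms, ranked by p then term id.
    """
    if not gmt:
        raise ValueError("empty gene-set collection")
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(genes) & uni
    rows = []
    for term_id in sorted(gmt):
        desc, members = gmt[term_id]
        members_u = members & uni
        hits = query & members_u
        p = float(
            stats.hypergeom.sf(len(hits) - 1, len(uni), len(members_u), len(query))
        )
        rows.append((term_id, desc, members_u, hits, p))
    q = bh_fdr([r[4] for r in rows])
    out = [
        EnrichedTerm(
            term_id=r[0],
            description=r[1],
            term_size=len(r[2]),
            hits=len(r[3]),
            p_value=r[4],
            fdr=float(qi),
            hit_genes=tuple(sorted(r[3])),
        )
        for r, qi in zip(rows, q)
    ]
    out.sort(key=lambda t: (t.p_value, t.term_id))
    return out


def enrichment_frame(terms: Sequence[EnrichedTerm]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": t.term_id,
                "description": t.description,
                "term_size": t.term_size,
                "hits": t.hits,
                "p": t.p_value,
                "fdr": t.fdr,
                "genes": ";".join(t.hit_genes),
            }
            for t in terms
        ],
        columns=["term", "description", "term_size", "hits", "p", "fdr", "genes"],
    )


def harmonize(genes: Iterable[str], ortholog_map: Mapping[str, str] | None = None) -> set[str]:
    """Case-insensitive symbol harmonisation with an optional ortholog map."""
    out = set()
    for g in genes:
        g = str(g)
        if ortholog_map and g in ortholog_map:
            g = ortholog_map[g]
        out.add(g.upper())
    return out


@dataclass
class IntegrationReport:
    deg_vs_peaks: OverlapResult
    rasg_vs_peaks: OverlapResult
    deg_direction_split: dict[str, int]  # up/down counts within DEG ∩ peaks
    deg_genes: tuple[str, ...]
    rasg_genes: tuple[str, ...]
    peak_genes: tuple[str, ...]


def integrate(
    deg_results: pd.DataFrame,
    rase_results: pd.DataFrame,
    peak_targets: Iterable[str],
    universe: Iterable[str],
    ortholog_map: Mapping[str, str] | None = None,
) -> IntegrationReport:
    """Overlap DEGs and RASGs with peak target genes over a shared universe.

    ``deg_results`` is the classified DEG table (status column); ``rase_results``
    the splicing test table (gene + significant columns).  Identifiers are
    harmonised to upper-cased symbols (optionally via an ortholog map)
    before testing.  The direction split partitions DEG ∩ peaks by status.
    """
    uni = harmonize(universe, ortholog_map)
    if not uni:
        raise ValueError("empty universe")
    status = deg_results["status"]
    deg_up = harmonize(deg_results.index[status == "up"], ortholog_map)
    deg_down = harmonize(deg_results.index[status == "down"], ortholog_map)
    deg = deg_up | deg_down
    if rase_results.empty:
        rasg: set[str] = set()
    else:
        sig = rase_results["significant"].fillna(False).astype(bool)
        rasg = harmonize(rase_results.loc[sig, "gene"], ortholog_map)
    peaks = harmonize(peak_targets, ortholog_map)

    deg_ov = hypergeom_overlap(deg, peaks, uni)
    rasg_ov = hypergeom_overlap(rasg, peaks, uni)
    overlapped = set(deg_ov.overlapped)
    split = {
        "up": len(overlapped & deg_up),
        "down": len(overlapped & deg_down),
    }
    return IntegrationReport(
        deg_vs_peaks=deg_ov,
        rasg_vs_peaks=rasg_ov,
        deg_direction_split=split,
        deg_genes=tuple(sorted(deg & uni)),
        rasg_genes=tuple(sorted(rasg & uni)),
        peak_genes=tuple(sorted(peaks & uni)),
    )
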
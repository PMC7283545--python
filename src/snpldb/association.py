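"""Association between multi-allelic SNPLDB markers and a two-category trait.

Two complementary analyses are provided, mirroring standard practice for
qualitative traits in germplasm panels:

* a single-locus Pearson chi-square scan on the H x 2 haplotype-by-category
  contingency table of every marker (no continuity correction, so the
  statistic is consistent across haplotype counts H), reported as
  -log10 p and selectable by top-K rank rather than a corrected threshold;
* a restricted two-stage multi-locus model ("RTM-GWAS-style"): markers
  passing a single-locus preselection are offered to a forward-backward
  stepwise least-squares fit of the 0/1-coded trait on haplotype indicator
  variables (most frequent haplotype as reference).  Entry and stay partial
  F-tests are Bonferroni-corrected for the number of markers scanned, which
  keeps the genome-wide false-entry rate near the nominal level.  Each
  selected locus is credited with its sequential (type-I) sum-of-squares
  share of the total phenotypic sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PhenotypeTable
from .snpldb_assembly import SNPLDBMarker

_P_FLOOR = 1e-300  # keep -log10 p finite


@dataclass
class AssociationResult:
    """Single-marker chi-square test on the haplotype x category table."""

    marker_id: str
    chrom: str
    pos: int
    haplotypes: list[str]
    categories: list[str]
    table: np.ndarray  # counts, shape (H, 2), zero rows already dropped
    chi2: float
    df: int
    p: float
    neg_log10_p: float
    degenerate: bool = False


def chi2_from_table(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Zero-total rows and columns are dropped first; a table reduced below
    2 x 2 is degenerate and returns (0, max(df,1), 1).
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 1, 1.0
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(max(p, _P_FLOOR))


def chi2_scan(
    markers: list[SNPLDBMarker],
    phenotype: PhenotypeTable,
    trait: str | None = None,
) -> list[AssociationResult]:
    """Chi-square association of every marker with a two-category trait.

    Results are sorted by descending -log10 p, ties broken by genomic order.
    Markers left with a single haplotype row are flagged degenerate (p = 1).
    """
    if trait is None:
        traits = phenotype.traits
        if len(traits) != 1:
            raise ValueError(f"specify trait; table has {traits}")
        trait = traits[0]
    categories = phenotype.categories(trait)
    if len(categories) != 2:
        raise ValueError(f"trait {trait!r} must have exactly two categories")
    pheno = phenotype.series(trait)
    results = []
    for m in markers:
        cats = pheno.reindex(m.accession_ids)
        if cats.isna().any():
            missing = [a for a, v in cats.items() if pd.isna(v)]
            raise ValueError(f"accessions without phenotype: {missing[:5]}")
        y = (cats.values == categories[1]).astype(int)
        H = m.n_haplotypes
        table = np.zeros((H, 2), dtype=int)
        np.add.at(table, (m.assignments, y), 1)
        row_keep = table.sum(axis=1) > 0
        haps = [h for h, k in zip(m.haplotypes, row_keep) if k]
        table = table[row_keep]
        degenerate = table.shape[0] < 2
        if degenerate:
            chi2, df, p = 0.0, 1, 1.0
        else:
            chi2, df, p = chi2_from_table(table)
            df = table.shape[0] - 1  # (H-1)(C-1) with C = 2
        results.append(
            AssociationResult(
                marker_id=m.marker_id,
                chrom=m.chrom,
                pos=m.start,
                haplotypes=haps,
                categories=list(categories),
                table=table,
                chi2=chi2,
                df=df,
                p=p,
                neg_log10_p=float(-np.log10(p)),
                degenerate=degenerate,
            )
        )
    results.sort(key=lambda r: (-r.neg_log10_p, r.chrom, r.pos))
    return results


def top_k(results: list[AssociationResult], k: int = 10) -> list[AssociationResult]:
    """The k most significant results (all of them if fewer are available)."""
    if not results:
        raise ValueError("no association results")
    ranked = sorted(results, key=lambda r: (-r.neg_log10_p, r.chrom, r.pos))
    return ranked[: min(k, len(ranked))]


# ---------------------------------------------------------------------------
# Multi-locus stepwise model


@dataclass
class MultiLocusModel:
    """Stepwise-selected marker set with variance contributions (% of total
    phenotypic sum of squares, sequential in selection order)."""

    marker_ids: list[str]
    contributions: list[float]
    total_r2: float
    p_enter: float
    p_stay: float
    preselect_p: float
    n_markers_scanned: int
    trait: str = ""

    def __post_init__(self) -> None:
        if any(c < -1e-9 for c in self.contributions):
            raise ValueError("negative variance contribution")
        if self.total_r2 > 100.0 + 1e-6:
            raise ValueError("total R^2 above 100%")


def _dummy_block(m: SNPLDBMarker) -> np.ndarray:
    """Indicator columns for all non-reference haplotypes present.

    Reference = most frequent haplotype (catalogue index 0)."""
    counts = np.bincount(m.assignments, minlength=m.n_haplotypes)
    cols = [
        (m.assignments == h).astype(float)
        for h in range(1, m.n_haplotypes)
        if counts[h] > 0
    ]
    if not cols:
        return np.empty((len(m.assignments), 0))
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """(residual sum of squares, rank) of least squares y ~ X."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _partial_f_p(
    rss0: float, rss1: float, q: int, n: int, rank1: int
) -> float:
    """p-value of the partial F test for q added columns."""
    df2 = n - rank1
    if df2 <= 0:
        return 1.0
    if rss1 <= 1e-12:  # saturated fit
        return 0.0
    f = ((rss0 - rss1) / q) / (rss1 / df2)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, q, df2))


def multilocus_stepwise(
    markers: list[SNPLDBMarker],
    phenotype: PhenotypeTable,
    p_enter: float = 0.05,
    p_stay: float = 0.05,
    preselect_p: float = 0.05,
    trait: str | None = None,
) -> MultiLocusModel:
    """Two-stage multi-locus model of a 0/1-coded two-category trait.

    Stage 1 keeps markers whose single-locus chi-square p is at most
    ``preselect_p``.  Stage 2 runs forward-backward stepwise least squares on
    haplotype indicators with partial F entry/stay tests at
    ``p_enter / m`` and ``p_stay / m`` where ``m`` is the number of markers
    scanned (Bonferroni, genome-wide control).  Deterministic given input
    order; rank-deficient additions (e.g. duplicated markers) are skipped
    with a warning.
    """
    scan = chi2_scan(markers, phenotype, trait=trait)
    by_id = {m.marker_id: m for m in markers}
    candidates = [r.marker_id for r in scan if not r.degenerate and r.p <= preselect_p]
    m_total = len(markers)
    enter_thresh = p_enter / max(1, m_total)
    stay_thresh = p_stay / max(1, m_total)

    categories = phenotype.categories(trait or phenotype.traits[0])
    pheno = phenotype.series(trait or phenotype.traits[0])
    acc = markers[0].accession_ids
    y = (pheno.reindex(acc).values == categories[1]).astype(float)
    n = y.size
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("phenotype has no variance")

    blocks = {mid: _dummy_block(by_id[mid]) for mid in candidates}
    selected: list[str] = []
    X = np.ones((n, 1))
    rss_cur, rank_cur = _rss(X, y)

    while True:
        best = None
        for mid in candidates:
            if mid in selected:
                continue
            B = blocks[mid]
            if B.shape[1] == 0:
                continue
            X_try = np.hstack([X, B])
            rss1, rank1 = _rss(X_try, y)
            q = rank1 - rank_cur
            if q == 0:
                warnings.warn(
                    f"marker {mid} adds no rank (collinear); skipped",
                    stacklevel=2,
                )
                continue
            p = _partial_f_p(rss_cur, rss1, q, n, rank1)
            if best is None or p < best[0]:
                best = (p, mid, X_try, rss1, rank1)
        if best is None or best[0] > enter_thresh:
            break
        _, mid, X, rss_cur, rank_cur = best
        selected.append(mid)

        # Backward pass: drop loci that no longer stay.
        changed = True
        while changed and len(selected) > 1:
            changed = False
            worst = None
            for mid_out in selected:
                others = [s for s in selected if s != mid_out]
                X_red = np.hstack([np.ones((n, 1))] + [blocks[s] for s in others])
                rss_red, rank_red = _rss(X_red, y)
                q = rank_cur - rank_red
                if q <= 0:
                    p_out = 1.0
                else:
                    p_out = _partial_f_p(rss_red, rss_cur, q, n, rank_cur)
                if p_out > stay_thresh and (worst is None or p_out > worst[0]):
                    worst = (p_out, mid_out)
            if worst is not None:
                selected.remove(worst[1])
                X = np.hstack([np.ones((n, 1))] + [blocks[s] for s in selected])
                rss_cur, rank_cur = _rss(X, y)
                changed = True

    # Sequential (type-I) sums of squares in selection order.
    contributions = []
    X_seq = np.ones((n, 1))
    rss_prev, _ = _rss(X_seq, y)
    for mid in selected:
        X_seq = np.hstack([X_seq, blocks[mid]])
        rss_next, _ = _rss(X_seq, y)
        contributions.append(100.0 * (rss_prev - rss_next) / ss_total)
        rss_prev = rss_next
    total_r2 = float(sum(contributions))
    return MultiLocusModel(
        marker_ids=selected,
        contributions=contributions,
        total_r2=total_r2,
        p_enter=p_enter,
        p_stay=p_stay,
        preselect_p=preselect_p,
        n_markers_scanned=m_total,
        trait=trait or phenotype.traits[0],
    )


# ---------------------------------------------------------------------------
# Manhattan plot


def plot_y_values(
    results: list[AssociationResult],
    truncate_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """-log10 p per result, with saturated p replaced by a random value
    log-uniform between ``truncate_p`` and ``truncate_p * 1e-5``."""
    lo = -np.log10(truncate_p)
    return np.array(
        [
            rng.uniform(lo, lo + 5.0) if r.p < truncate_p else r.neg_log10_p
            for r in results
        ]
    )


def manhattan_plot(
    results: list[AssociationResult],
    out_path,
    truncate_p: float = 1e-50,
    seed: int = 0,
) -> None:
    """Genome-wide scatter of -log10 p with chromosome-alternating colours.

    Extremely small p-values (below ``truncate_p``) are replaced by a seeded
    random value log-uniform between 1e-55 and 1e-50 so a single saturated
    locus does not flatten the rest of the scan.
    """
    if not results:
        raise ValueError("no association results to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    ordered = sorted(results, key=lambda r: (r.chrom, r.pos))
    chroms = list(dict.fromkeys(r.chrom for r in ordered))
    offsets, off = {}, 0
    for c in chroms:
        offsets[c] = off
        off += max(r.pos for r in ordered if r.chrom == c) + 1
    xs = np.array([offsets[r.chrom] + r.pos for r in ordered], dtype=float)
    ys = plot_y_values(ordered, truncate_p, rng)
    colors = ["#1f77b4", "#ff7f0e"]
    cidx = np.array([chroms.index(r.chrom) % 2 for r in ordered])
    fig, ax = plt.subplots(figsize=(8, 3))
    for k in (0, 1):
        mask = cidx == k
        ax.scatter(xs[mask], ys[mask], s=8, c=colors[k], linewidths=0)
    ax.set_xlabel("genomic position")
    ax.set_ylabel(r"$-\log_{10}p$")
    ax.set_xticks([offsets[c] + 1 for c in chroms])
    ax.set_xticklabels(chroms)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Result tables


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in results],
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "n_haplotypes": [len(r.haplotypes) for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


def frame_to_results(frame: pd.DataFrame) -> list[AssociationResult]:
    """Rebuild lightweight results (no tables) from a results TSV frame."""
    out = []
    for _, r in frame.iterrows():
        out.append(
            AssociationResult(
                marker_id=r["marker_id"],
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                haplotypes=[],
                categories=[],
                table=np.zeros((0, 2)),
                chi2=float(r["chi2"]),
                df=int(r["df"]),
                p=float(r["p"]),
                neg_log10_p=float(r["neg_log10_p"]),
                degenerate=bool(r.get("degenerate", False)),
            )
        )
    return out
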
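"""Chi-square scan, top-K selection, stepwise multi-locus model, plotting."""

import warnings

import numpy as np
import pandas as pd
import pytest

import snpldb as s
from snpldb.association import plot_y_values, results_to_frame

from conftest import make_phenotype, two_hap_config


def chi2_oracle(table):
    """Textbook Pearson chi-square with explicit expected counts."""
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    return ((t - expected) ** 2 / expected).sum()


def _marker_from_labels(labels, accession_ids, marker_id="m1", pos=100):
    """Marker whose haplotype classes are the given per-accession labels."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    catalogue = [str(uniq[i]) for i in order]
    lookup = {h: i for i, h in enumerate(catalogue)}
    return s.SNPLDBMarker(
        marker_id=marker_id, chrom="c1", start=pos, end=pos,
        snp_ids=["s1"], haplotypes=catalogue,
        frequencies=counts[order] / len(labels),
        assignments=np.array([lookup[str(l)] for l in labels]),
        accession_ids=list(accession_ids),
    )


class TestChi2:
    def test_independent_table_gives_zero(self):
        chi2, df, p = s.chi2_from_table([[50, 50], [50, 50]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_2x2(self):
        """Perfectly associated balanced 2x2 table: chi-square equals n."""
        chi2, df, p = s.chi2_from_table([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_fixture_pooled_table_matches_oracle(self):
        """Pooled 5x2 flower-colour haplotype table recomputes identically
        with the explicit expected-count formula."""
        ft = s.fixture_frequency_table("FC-1")
        pooled = (
            ft.pheno_counts.T.groupby(level=1).sum().T
        )  # haplotype x category over all populations
        table = pooled.values
        chi2, df, p = s.chi2_from_table(table)
        assert chi2 == pytest.approx(chi2_oracle(table), rel=1e-12)
        assert df == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_row_column_permutation_invariance(self, rng):
        table = rng.integers(0, 50, size=(4, 2))
        table[0, 0] += 5
        base, _, _ = s.chi2_from_table(table)
        perm, _, _ = s.chi2_from_table(table[::-1, ::-1])
        assert perm == pytest.approx(base, rel=1e-12)

    def test_random_tables_match_oracle(self, rng):
        """Scan chi-square equals the independent textbook formula on random
        H x 2 tables."""
        for _ in range(300):
            H = rng.integers(2, 7)
            table = rng.integers(0, 40, size=(H, 2))
            if table.sum() == 0:
                continue
            got, _, _ = s.chi2_from_table(table)
            assert got == pytest.approx(chi2_oracle(table), rel=1e-10, abs=1e-10)


class TestScan:
    def test_scan_orders_by_significance(self, rng):
        acc = [f"A{i}" for i in range(100)]
        y = np.array(["a"] * 50 + ["b"] * 50)
        causal = _marker_from_labels(y, acc, "causal", pos=100)
        noise = _marker_from_labels(
            rng.permutation(y), acc, "noise", pos=200
        )
        phen = make_phenotype(acc, y)
        res = s.chi2_scan([noise, causal], phen)
        assert res[0].marker_id == "causal"
        assert res[0].p < 1e-10

    def test_degenerate_single_haplotype_flagged(self):
        acc = [f"A{i}" for i in range(10)]
        m = _marker_from_labels(["x"] * 10, acc)
        phen = make_phenotype(acc, ["a"] * 5 + ["b"] * 5)
        res = s.chi2_scan([m], phen)
        assert res[0].degenerate
        assert res[0].p == 1.0

    def test_top_k_returns_all_when_few(self, rng):
        acc = [f"A{i}" for i in range(20)]
        y = ["a"] * 10 + ["b"] * 10
        markers = [
            _marker_from_labels(rng.permutation(y), acc, f"m{j}", pos=100 * (j + 1))
            for j in range(3)
        ]
        res = s.chi2_scan(markers, make_phenotype(acc, y))
        assert len(s.top_k(res, 10)) == 3

    def test_top_k_tiebreak_by_genomic_order(self):
        acc = [f"A{i}" for i in range(8)]
        y = ["a"] * 4 + ["b"] * 4
        labels = ["h1", "h1", "h2", "h2"] * 2
        m_late = _marker_from_labels(labels, acc, "late", pos=500)
        m_early = _marker_from_labels(labels, acc, "early", pos=100)
        res = s.chi2_scan([m_late, m_early], make_phenotype(acc, y))
        assert [r.marker_id for r in s.top_k(res, 2)] == ["early", "late"]


class TestMultilocus:
    def test_saturated_marker_takes_all_variance(self):
        acc = [f"A{i}" for i in range(60)]
        y = np.array(["a"] * 30 + ["b"] * 30)
        m = _marker_from_labels(y, acc, "m1")
        model = s.multilocus_stepwise([m], make_phenotype(acc, y))
        assert model.marker_ids == ["m1"]
        assert model.contributions[0] == pytest.approx(100.0, abs=1e-6)

    def test_duplicated_marker_changes_nothing(self, rng):
        acc = [f"A{i}" for i in range(200)]
        h = rng.integers(0, 2, size=200)
        y = np.where((rng.random(200) < 0.85) == (h == 1), "b", "a")
        m1 = _marker_from_labels(h, acc, "m1", pos=100)
        dup = _marker_from_labels(h, acc, "dup", pos=200)
        phen = make_phenotype(acc, y)
        base = s.multilocus_stepwise([m1], phen)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            both = s.multilocus_stepwise([m1, dup], phen)
        assert both.marker_ids[0] == base.marker_ids[0]
        assert both.contributions[0] == pytest.approx(
            base.contributions[0], abs=1e-9
        )

    def test_two_locus_contributions_recover_truth(self):
        """Stepwise sequential contributions match an oracle regression on
        the true causal assignments."""
        errs = []
        for seed in range(5):
            res = _two_locus_experiment(seed)
            errs.append(max(abs(res["err1"]), abs(res["err2"])))
            assert set(res["selected"]) == {res["id1"], res["id2"]}
        assert np.mean(errs) <= 5.0

    def test_null_trait_selects_almost_nothing(self, clean_markers, clean_sim):
        g, *_ = clean_sim
        rng = np.random.default_rng(7)
        informative = [m for m in clean_markers if m.n_haplotypes >= 2]
        sizes = []
        for _ in range(5):
            y = np.where(rng.random(g.n_accessions) < 0.5, "a", "b")
            phen = make_phenotype(g.accession_ids, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = s.multilocus_stepwise(informative, phen)
            sizes.append(len(model.marker_ids))
        assert sum(sz <= 1 for sz in sizes) >= 4

    def test_monotone_chi2_in_penetrance_separation(self):
        """Widening the penetrance gap between two haplotypes does not
        decrease the causal chi-square on average."""
        def mean_chi2(gap, seeds=range(4)):
            vals = []
            for seed in seeds:
                cfg = two_hap_config(
                    seed=seed, pen=(0.5 + gap / 2, 0.5 - gap / 2)
                )
                g, phen, meta, truth = s.simulate_population(cfg)
                markers = s.assemble_markers(g)
                res = s.chi2_scan(markers, phen)
                causal = truth.blocks[
                    truth.block_index(truth.primary_block_id)
                ]
                hit = next(
                    r for r in res
                    for m in markers
                    if m.marker_id == r.marker_id
                    and set(m.snp_ids) & set(causal.snp_ids)
                )
                vals.append(hit.chi2)
            return np.mean(vals)

        assert mean_chi2(0.8) > mean_chi2(0.3)


def _two_locus_experiment(seed):
    """Two independent 50/50 biallelic causal loci driving a binary trait
    additively (target shares ~ 40%/20%); returns stepwise vs oracle shares."""
    from snpldb.io_formats import SUBPOPULATIONS

    sizes = {sp: 83 for sp in SUBPOPULATIONS}
    sizes["WA_I"] = 87  # total 1,000
    h1 = s.staircase_haplotypes(5, 2)
    h2 = s.staircase_haplotypes(4, 2)
    flat = {p: [0.5, 0.5] for p in ("WA", "LR", "RC")}
    none = {"WA": 0.0, "LR": 0.0, "RC": 0.0}
    spec1 = s.CausalLocusSpec(0, 5, h1, flat, {h: dict(none) for h in h1})
    spec2 = s.CausalLocusSpec(1, 6, h2, flat, {h: dict(none) for h in h2})
    cfg = s.SimulationConfig(
        n_accessions_per_subpop=sizes, causal_blocks=[spec1, spec2],
        missing_rate=0.0, het_rate=0.0, seed=seed,
    )
    g, _, meta, truth = s.simulate_population(cfg)
    rng = np.random.default_rng(10_000 + seed)
    x1 = truth.assignments[:, truth.block_index("Gm01_B05")]
    x2 = truth.assignments[:, truth.block_index("Gm02_B06")]
    p = np.clip(0.6325 * x1 + 0.4472 * x2, 0.0, 1.0)
    y = rng.random(p.size) < p
    phen = make_phenotype(g.accession_ids, np.where(y, "b", "a"))

    markers = s.assemble_markers(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = s.multilocus_stepwise(markers, phen)

    # Oracle: sequential regression on the true assignments.
    yf = y.astype(float)
    sst = ((yf - yf.mean()) ** 2).sum()
    X1 = np.column_stack([np.ones_like(yf), x1])
    r1 = yf - X1 @ np.linalg.lstsq(X1, yf, rcond=None)[0]
    X2 = np.column_stack([X1, x2])
    r2 = yf - X2 @ np.linalg.lstsq(X2, yf, rcond=None)[0]
    share1 = 100 * (sst - (r1 ** 2).sum()) / sst
    share2 = 100 * ((r1 ** 2).sum() - (r2 ** 2).sum()) / sst

    by_id = dict(zip(model.marker_ids, model.contributions))
    id1 = next(m.marker_id for m in markers if "Gm01_750001" in m.marker_id)
    id2 = next(m.marker_id for m in markers if "Gm02_900001" in m.marker_id)
    return {
        "selected": model.marker_ids,
        "id1": id1,
        "id2": id2,
        "err1": by_id.get(id1, 0.0) - share1,
        "err2": by_id.get(id2, 0.0) - share2,
    }


class TestManhattan:
    def _results(self, ps):
        out = []
        for i, p in enumerate(ps):
            out.append(
                s.AssociationResult(
                    marker_id=f"m{i}", chrom="c1", pos=100 * (i + 1),
                    haplotypes=[], categories=[], table=np.zeros((0, 2)),
                    chi2=0.0, df=1, p=p,
                    neg_log10_p=float(-np.log10(p)),
                )
            )
        return out

    def test_plot_file_written(self, tmp_path):
        res = self._results(np.linspace(0.01, 1.0, 100))
        out = tmp_path / "m.png"
        s.manhattan_plot(res, out)
        assert out.exists() and out.stat().st_size > 0

    def test_saturated_p_truncated_into_band(self):
        res = self._results([1e-60, 0.5])
        ys = plot_y_values(res, 1e-50, np.random.default_rng(0))
        assert 50.0 <= ys[0] <= 55.0
        assert ys[1] == pytest.approx(-np.log10(0.5))

    def test_all_p_one_plots_at_zero(self):
        res = self._results([1.0, 1.0, 1.0])
        ys = plot_y_values(res, 1e-50, np.random.default_rng(0))
        assert np.allclose(ys, 0.0)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            s.manhattan_plot([], tmp_path / "x.png")


def test_results_frame_roundtrip(rng):
    acc = [f"A{i}" for i in range(20)]
    y = ["a"] * 10 + ["b"] * 10
    markers = [
        _marker_from_labels(rng.permutation(y), acc, f"m{j}", pos=100 * (j + 1))
        for j in range(3)
    ]
    res = s.chi2_scan(markers, make_phenotype(acc, y))
    frame = results_to_frame(res)
    back = s.association.frame_to_results(frame)
    assert [r.marker_id for r in back] == [r.marker_id for r in res]
    assert [r.p for r in back] == pytest.approx([r.p for r in res])
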
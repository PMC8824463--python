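import hashlib
import io
import math
from pathlib import Path

import numpy as np
import pytest

from phosphoquad import PipelineParameters
from phosphoquad import io as pq_io
from phosphoquad.model import PipelineError, Region
from phosphoquad.motifs import classify_motif
from phosphoquad.pipeline import run_pipeline
from phosphoquad.quantify import eliminate_missing
from phosphoquad.simulate import (
    GeneratorConfig,
    evaluate_recovery,
    generate_dataset,
    generate_proteome,
    write_dataset,
)


def records_from(dataset):
    records = []
    for table in dataset.quant_tables.values():
        buf = io.StringIO()
        table.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        recs, rejections = pq_io.read_quant_table(buf, dataset.designs)
        assert rejections == []
        records.extend(recs)
    return records


class TestGenerateProteome:
    def test_byte_identical_across_runs(self, tmp_path):
        digests = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            paths = write_dataset(generate_dataset(GeneratorConfig(n_sites=50, n_proteins=20), 11), d)
            digests.append(
                tuple(hashlib.sha256(Path(p).read_bytes()).hexdigest() for _, p in sorted(paths.items()))
            )
        assert digests[0] == digests[1]

    def test_forced_stq_planting_rate(self):
        cfg = GeneratorConfig(
            n_sites=60,
            n_proteins=20,
            motif_rates={"Q2": {"STQ": 1.0}, "default": {"STQ": 1.0}},
        )
        proteome, placements = generate_proteome(cfg, 5)
        for row in placements.itertuples(index=False):
            assert row.window[7] == "Q"  # +1 position of the 13-mer window
            assert classify_motif(row.window).value == "STQ"

    def test_background_plus_one_q_rate_within_binomial_ci(self):
        rate = 0.05
        cfg = GeneratorConfig(
            n_sites=2000,
            n_proteins=400,
            motif_rates={"default": {"STQ": rate, "STPXK": 0.0, "STP_OTHER": 0.0}},
            class_proportions={"CENTER": 1.0, "Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0},
        )
        _, placements = generate_proteome(cfg, 9)
        observed = np.mean([row.window[7] == "Q" for row in placements.itertuples(index=False)])
        half_width = 1.96 * math.sqrt(rate * (1 - rate) / cfg.n_sites)
        assert abs(observed - rate) < half_width + 0.005

    def test_site_density_infeasible_raises(self):
        with pytest.raises(PipelineError):
            generate_proteome(GeneratorConfig(n_sites=100000, n_proteins=2), 0)

    def test_class_counts_within_three_binomial_sd(self):
        props = {"Q2": 0.1, "Q1": 0.1, "Q3": 0.1, "Q4": 0.1, "CENTER": 0.6}
        cfg = GeneratorConfig(n_sites=5000, n_proteins=600, class_proportions=props)
        _, placements = generate_proteome(cfg, 13)
        counts = placements["true_class"].value_counts()
        for cls, p in props.items():
            sd = math.sqrt(cfg.n_sites * p * (1 - p))
            assert abs(counts.get(cls, 0) - cfg.n_sites * p) <= 3 * sd


class TestGenerateDataset:
    def test_zero_noise_q2_effect_recovered_exactly(self):
        cfg = GeneratorConfig(
            n_sites=50,
            n_proteins=20,
            noise_sd=0.0,
            dropout=0.0,
            ambiguity_prob=0.0,
            class_proportions={"Q2": 0.2, "CENTER": 0.8, "Q1": 0, "Q3": 0, "Q4": 0},
            effect_sizes={
                "Q2": ((-2.0, 0.0), (-2.0, 0.0)),
                "CENTER": ((0.0, 0.0), (0.0, 0.0)),
                "Q1": ((0.0, 0.1), (-1.5, 0.3)),
                "Q3": ((-1.5, 0.3), (0.0, 0.1)),
                "Q4": ((1.5, 0.3), (1.5, 0.3)),
            },
        )
        ds = generate_dataset(cfg, 3)
        result = run_pipeline(records_from(ds), ds.designs, ds.proteome, PipelineParameters())
        truth_class = {
            (t.protein, t.position): t.true_class for t in ds.truth.itertuples(index=False)
        }
        for site in result.merged_sites:
            expected = -2.0 if truth_class[site.site_key] == "Q2" else 0.0
            # intensities are serialized with 4 decimals, so exactness is ~1e-6
            assert site.x == pytest.approx(expected, abs=1e-6)
            assert site.y == pytest.approx(expected, abs=1e-6)

    def test_full_dropout_eliminates_every_record(self):
        ds = generate_dataset(GeneratorConfig(n_sites=20, n_proteins=10, dropout=1.0), 2)
        records = records_from(ds)
        by_exp = {d.experiment_id: d for d in ds.designs}
        assert records and eliminate_missing(records, by_exp) == []
        ds2 = generate_dataset(GeneratorConfig(n_sites=20, n_proteins=10, dropout=0.0), 2)
        by_exp2 = {d.experiment_id: d for d in ds2.designs}
        assert len(eliminate_missing(records_from(ds2), by_exp2)) == 20 * len(ds2.designs)

    def test_generated_tables_validate_with_zero_rejections(self):
        ds = generate_dataset(GeneratorConfig(n_sites=100, n_proteins=30), 4)
        records = records_from(ds)  # records_from asserts zero rejections
        assert len(records) == 100 * len(ds.designs)

    def test_ambiguous_sites_cluster_back_to_true_position(self):
        cfg = GeneratorConfig(n_sites=100, n_proteins=30, ambiguity_prob=1.0, noise_sd=0.0, dropout=0.0)
        ds = generate_dataset(cfg, 6)
        result = run_pipeline(records_from(ds), ds.designs, ds.proteome, PipelineParameters())
        truth_keys = {(t.protein, t.position) for t in ds.truth.itertuples(index=False)}
        assert {s.site_key for s in result.merged_sites} == truth_keys
        assert all(len(s.clustered_positions) == 2 for s in result.merged_sites)

    def test_low_confidence_sites_removed_by_localization_filter(self):
        cfg = GeneratorConfig(n_sites=100, n_proteins=30, low_confidence_fraction=1.0)
        ds = generate_dataset(cfg, 8)
        result = run_pipeline(records_from(ds), ds.designs, ds.proteome, PipelineParameters())
        assert result.merged_sites == []

    def test_planted_inverted_replicates_fail_consistency(self):
        cfg = GeneratorConfig(
            n_sites=200,
            n_proteins=60,
            inverted_replicate_fraction=1.0,
            noise_sd=0.05,
            dropout=0.0,
        )
        ds = generate_dataset(cfg, 10)
        result = run_pipeline(records_from(ds), ds.designs, ds.proteome, PipelineParameters())
        truth_class = {
            (t.protein, t.position): t.true_class for t in ds.truth.itertuples(index=False)
        }
        q2 = [
            a
            for s, a in zip(result.merged_sites, result.assignments)
            if truth_class[s.site_key] == "Q2" and a.region is Region.Q2
        ]
        assert q2 and all(a.passed_consistency is False for a in q2)


class TestEvaluateRecovery:
    def test_perfect_assignment(self):
        ds = generate_dataset(GeneratorConfig(n_sites=50, n_proteins=20), 12)
        assignments = {
            (t.protein, t.position): t.true_class for t in ds.truth.itertuples(index=False)
        }
        report = evaluate_recovery(assignments, ds.truth)
        for cls in ("Q2", "CENTER"):
            assert report.recall[cls] == 1.0
            assert report.precision[cls] == 1.0
        assert int(report.confusion.to_numpy().sum()) == 50

    def test_all_center_prediction_zeroes_q2_recall(self):
        ds = generate_dataset(GeneratorConfig(n_sites=50, n_proteins=20), 12)
        assignments = {
            (t.protein, t.position): Region.CENTER for t in ds.truth.itertuples(index=False)
        }
        report = evaluate_recovery(assignments, ds.truth)
        assert report.recall["Q2"] == 0.0

    def test_unknown_key_is_error(self):
        ds = generate_dataset(GeneratorConfig(n_sites=20, n_proteins=10), 12)
        with pytest.raises(PipelineError):
            evaluate_recovery({("NOPE", 1): Region.CENTER}, ds.truth)

    def test_missing_sites_count_against_recall(self):
        ds = generate_dataset(GeneratorConfig(n_sites=50, n_proteins=20), 12)
        report = evaluate_recovery({}, ds.truth)
        assert all(r == 0.0 for r in report.recall.values() if not math.isnan(r))
        assert int(report.confusion["MISSING"].sum()) == 50
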
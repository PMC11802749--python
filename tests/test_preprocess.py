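"""Retention filtering: config loading, criteria semantics, streaming runs."""

import gzip
import json

import numpy as np
import pytest

from varcurate.errors import ConfigError
from varcurate.fixtures import GeneratorSpec, generate_random_vcf
from varcurate.preprocess import (
    CRITERION_ORDER,
    FilterConfig,
    config_from_dict,
    filter_file,
    genes_of,
    load_filter_config,
    record_passes,
    reduce_record,
)
from varcurate.vcf_io import iter_records, read_header


class TestConfigLoading:
    def test_inline_and_file_lists_merge(self, tmp_path):
        (tmp_path / "genes.txt").write_text("# panel\nBAG3\n")
        cfg_path = tmp_path / "cfg.json"
        cfg_path.write_text(
            json.dumps({"gene_symbols": ["TTN"], "gene_symbols_file": "genes.txt"})
        )
        config = load_filter_config(cfg_path)
        assert config.gene_symbols == {"TTN", "BAG3"}

    def test_empty_object_is_identity_config(self, tmp_path):
        cfg_path = tmp_path / "cfg.json"
        cfg_path.write_text("{}")
        config = load_filter_config(cfg_path)
        assert not config.genes_active
        assert config.qual_min is None and not config.variant_ids
        assert config.missing_passes is True

    def test_inverted_frequency_window_rejected(self):
        with pytest.raises(ConfigError):
            config_from_dict({"allele_freq": {"min": 0.6, "max": 0.4}})

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="no_such_key"):
            config_from_dict({"no_such_key": 1})

    def test_missing_list_file_is_io_error(self, tmp_path):
        from varcurate.errors import InputOutputError

        with pytest.raises(InputOutputError):
            config_from_dict({"variant_ids_file": "nope.txt"}, base_dir=tmp_path)


class TestGenesOf:
    def test_ann_entry_yields_pair(self, mini_vcf):
        header = read_header(mini_vcf)
        records = list(iter_records(mini_vcf, header))
        assert ("TTN", "ENSG00000155657") in genes_of(records[1], header)

    def test_record_without_annotation_is_empty(self, mini_vcf):
        header = read_header(mini_vcf)
        records = list(iter_records(mini_vcf, header))
        assert genes_of(records[0], header) == set()

    def test_multiple_ann_entries_union(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[1]
        ann = rec.info["ANN"]
        second = ann.replace("TTN", "BAG3").replace("ENSG00000155657", "ENSG00000151929")
        rec.info["ANN"] = f"{ann},{second}"
        pairs = genes_of(rec, header)
        assert {"TTN", "BAG3"} <= {sym for sym, _ in pairs}

    def test_gene_info_key_contributes(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[0]
        rec.info["GENE"] = "SCN5A"
        assert ("SCN5A", None) in genes_of(rec, header)


class TestRecordPasses:
    def test_variant_id_match_keeps(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[0]
        rec.id = "rs11590635"
        keep, _ = record_passes(rec, FilterConfig(variant_ids={"rs11590635"}), header)
        assert keep

    def test_qual_below_minimum_attributed(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[0]
        rec.qual = 29.5
        keep, why = record_passes(rec, FilterConfig(qual_min=30), header)
        assert (keep, why) == (False, "qual_min")

    def test_missing_qual_passes_by_default(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[1]  # QUAL "."
        assert record_passes(rec, FilterConfig(qual_min=30), header) == (True, None)

    def test_missing_qual_drops_when_strict(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[1]
        keep, why = record_passes(
            rec, FilterConfig(qual_min=30, missing_passes=False), header
        )
        assert (keep, why) == (False, "qual_min")

    def test_gene_symbol_match_case_insensitive(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[1]
        keep, _ = record_passes(rec, FilterConfig(gene_symbols={"ttn"}), header)
        assert keep

    def test_ensembl_id_match(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[1]
        keep, _ = record_passes(
            rec, FilterConfig(ensembl_gene_ids={"ENSG00000155657"}), header
        )
        assert keep

    def test_first_failing_criterion_attributed(self, mini_vcf):
        """FILTER is checked before QUAL, so q10 wins the attribution."""
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[2]  # FILTER=q10, QUAL=9.5
        config = FilterConfig(filter_pass_only=True, qual_min=30)
        keep, why = record_passes(rec, config, header)
        assert (keep, why) == (False, "filter_pass_only")
        assert CRITERION_ORDER.index("filter_pass_only") < CRITERION_ORDER.index("qual_min")

    def test_allele_freq_window(self, mini_vcf):
        header = read_header(mini_vcf)
        recs = list(iter_records(mini_vcf, header))
        config = FilterConfig(allele_freq_min=0.2, allele_freq_max=0.6)
        assert record_passes(recs[0], config, header)[0]  # AF=0.5
        assert record_passes(recs[1], config, header)[0]  # AF=0.25 (first value)
        assert record_passes(recs[2], config, header) == (False, "allele_freq")  # 0.9


class TestReduceRecord:
    def test_info_projection(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[1]
        out = reduce_record(rec, FilterConfig(info_keys_keep=["ANN"]), header)
        assert list(out.info) == ["ANN"]

    def test_keep_all_samples_is_identity(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[0]
        out = reduce_record(rec, FilterConfig(samples_keep=["S1", "S2"]), header)
        assert out == rec

    def test_sample_projection(self, mini_vcf):
        header = read_header(mini_vcf)
        rec = list(iter_records(mini_vcf, header))[0]
        out = reduce_record(rec, FilterConfig(samples_keep=["S2"]), header)
        assert len(out.samples) == 1
        assert out.samples[0] == rec.samples[1]

    def test_unknown_sample_rejected_before_streaming(self, mini_vcf, tmp_path):
        with pytest.raises(ConfigError, match="S9"):
            filter_file(mini_vcf, tmp_path / "o.vcf", FilterConfig(samples_keep=["S9"]))
        assert not (tmp_path / "o.vcf").exists()


# ---------------------------------------------------------------------------
# streaming runs


def reference_filter(path, config):
    """Naive in-memory oracle: load everything, re-derive each criterion."""
    header = read_header(path)
    out = []
    for rec in iter_records(path, header):
        ok = True
        if config.filter_pass_only:
            ok = rec.filter == "PASS" or (rec.filter == "." and config.missing_passes)
        if ok and config.variant_ids:
            ok = rec.id in config.variant_ids if rec.id else config.missing_passes
        if ok and (config.gene_symbols or config.ensembl_gene_ids):
            pairs = genes_of(rec, header)
            if not pairs:
                ok = config.missing_passes
            else:
                ok = any(
                    s.upper() in {g.upper() for g in config.gene_symbols}
                    or (e is not None and e in config.ensembl_gene_ids)
                    for s, e in pairs
                )
        if ok and config.qual_min is not None:
            ok = rec.qual >= config.qual_min if rec.qual is not None else config.missing_passes
        if ok and (config.allele_freq_min is not None or config.allele_freq_max is not None):
            raw = rec.info_value(config.allele_freq_key)
            try:
                value = float(raw.split(",")[0]) if raw is not None else None
            except ValueError:
                value = None
            if value is None:
                ok = config.missing_passes
            else:
                lo = config.allele_freq_min or 0.0
                hi = config.allele_freq_max if config.allele_freq_max is not None else 1.0
                ok = lo <= value <= hi
        if ok:
            for key, minimum in config.score_thresholds:
                raw = rec.info_value(key)
                try:
                    value = float(raw.split(",")[0]) if raw is not None else None
                except ValueError:
                    value = None
                if value is None:
                    ok = config.missing_passes
                else:
                    ok = value >= minimum
                if not ok:
                    break
        if ok:
            out.append(reduce_record(rec, config, header))
    return out


class TestFilterFile:
    def test_identity_config_keeps_everything(self, cohort_vcf, tmp_path):
        path, truth = cohort_vcf
        stats = filter_file(path, tmp_path / "o.vcf", FilterConfig())
        assert stats.records_kept == stats.records_read == len(truth["variants"])
        assert list(iter_records(tmp_path / "o.vcf")) == list(iter_records(path))

    def test_planted_panel_hits_recovered(self, tmp_path, gene_panel):
        path, truth = generate_random_vcf(
            tmp_path / "r.vcf",
            GeneratorSpec(seed=21, n_records=200, n_samples=2, n_panel_records=30),
        )
        config = FilterConfig(gene_symbols=gene_panel.gene_symbols, missing_passes=False)
        stats = filter_file(path, tmp_path / "o.vcf", config)
        assert stats.records_kept == 30
        kept_ids = {v["index"] for v in truth["variants"] if v["on_panel"]}
        kept_pos = {(r.chrom, r.pos) for r in iter_records(tmp_path / "o.vcf")}
        expected = {
            (v["chrom"], v["pos"]) for v in truth["variants"] if v["index"] in kept_ids
        }
        assert kept_pos == expected

    def test_worker_counts_byte_identical(self, tmp_path):
        path, _ = generate_random_vcf(
            tmp_path / "r.vcf", GeneratorSpec(seed=22, n_records=150, n_samples=3)
        )
        outs = []
        for w in (1, 4):
            out = tmp_path / f"o{w}.vcf"
            filter_file(path, out, FilterConfig(qual_min=50, workers=w))
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_stats_partition_drops(self, tmp_path):
        path, _ = generate_random_vcf(
            tmp_path / "r.vcf", GeneratorSpec(seed=23, n_records=120, n_samples=2)
        )
        config = FilterConfig(filter_pass_only=True, qual_min=60, missing_passes=False)
        stats = filter_file(path, tmp_path / "o.vcf", config)
        assert stats.records_kept + sum(stats.drops_by_criterion.values()) == 120
        assert set(stats.drops_by_criterion) <= set(CRITERION_ORDER)
        assert stats.started_at is not None and stats.finished_at is not None

    def test_timestamped_log_written(self, mini_vcf, tmp_path):
        log_dir = tmp_path / "logs"
        filter_file(mini_vcf, tmp_path / "o.vcf", FilterConfig(), log_dir=log_dir)
        logs = list(log_dir.glob("preprocess-*.log"))
        manifests = list(log_dir.glob("preprocess-*-manifest.json"))
        assert len(logs) == 1 and len(manifests) == 1
        manifest = json.loads(manifests[0].read_text())
        assert manifest["success"] and manifest["stats"]["records_read"] == 3

    def test_monotonicity_adding_criterion(self, tmp_path):
        path, _ = generate_random_vcf(
            tmp_path / "r.vcf", GeneratorSpec(seed=24, n_records=100, n_samples=2)
        )
        base = filter_file(path, tmp_path / "a.vcf", FilterConfig(qual_min=50))
        tighter = filter_file(
            path, tmp_path / "b.vcf", FilterConfig(qual_min=50, filter_pass_only=True)
        )
        assert tighter.records_kept <= base.records_kept


def _random_config(rng, truth, panel_genes):
    """Draw a random but consistent FilterConfig for a generated file."""
    config = FilterConfig()
    config.missing_passes = bool(rng.random() < 0.7)
    if rng.random() < 0.3:
        config.filter_pass_only = True
    if rng.random() < 0.3:
        ids = [v["rsid"] for v in truth["variants"] if v["rsid"]]
        if ids:
            take = rng.choice(len(ids), size=min(len(ids), 5), replace=False)
            config.variant_ids = {ids[i] for i in take}
    if rng.random() < 0.4:
        config.gene_symbols = set(
            rng.choice(panel_genes, size=int(rng.integers(1, 6)), replace=False)
        )
    if rng.random() < 0.4:
        config.qual_min = float(rng.uniform(30, 90))
    if rng.random() < 0.3:
        lo, hi = sorted(rng.uniform(0, 1, size=2).round(3))
        config.allele_freq_min, config.allele_freq_max = float(lo), float(hi)
    if rng.random() < 0.3:
        config.score_thresholds = [("DP", float(rng.uniform(100, 4000)))]
    if rng.random() < 0.3:
        # keep the projection consistent: never project away a key some
        # other criterion tests, or idempotence cannot hold
        config.info_keys_keep = ["AF", "ANN"] + (
            ["DP"] if config.score_thresholds else []
        )
    if rng.random() < 0.3:
        n = int(rng.integers(1, truth["n_samples"] + 1))
        names = [f"S{i + 1:03d}" for i in range(truth["n_samples"])]
        config.samples_keep = sorted(
            str(s) for s in rng.choice(names, size=n, replace=False)
        )
    return config


def test_filter_oracle_property_suite(tmp_path, gene_panel):
    """Streaming filter == in-memory reference, worker- and
    compression-invariant, and idempotent, across 100 random instances."""
    rng = np.random.default_rng(20240917)
    panel_genes = sorted(gene_panel.gene_symbols)
    for trial in range(100):
        spec = GeneratorSpec(
            seed=int(rng.integers(0, 2**31)),
            n_records=int(rng.integers(10, 80)),
            n_samples=int(rng.integers(1, 9)),
            n_panel_records=int(rng.integers(0, 8)),
            missing_qual_fraction=float(rng.uniform(0, 0.5)),
            missing_id_fraction=float(rng.uniform(0, 0.5)),
            multi_allelic_fraction=float(rng.uniform(0, 0.3)),
        )
        spec.n_panel_records = min(spec.n_panel_records, spec.n_records)
        work = tmp_path / f"t{trial}"
        work.mkdir()
        path, truth = generate_random_vcf(work / "in.vcf", spec, panel_genes=panel_genes)
        config = _random_config(rng, truth, panel_genes)

        out1 = work / "out1.vcf"
        filter_file(path, out1, config)
        got = list(iter_records(out1))
        expected = reference_filter(path, config)
        assert got == expected, f"trial {trial}: streaming != reference"

        for workers in (2, 4):
            config.workers = workers
            out_w = work / f"out{workers}.vcf"
            filter_file(path, out_w, config)
            assert out_w.read_bytes() == out1.read_bytes(), f"trial {trial} w={workers}"
        config.workers = 1

        gz = work / "in.vcf.gz"
        gz.write_bytes(gzip.compress(path.read_bytes()))
        out_gz = work / "out_gz.vcf"
        filter_file(gz, out_gz, config)
        assert out_gz.read_bytes() == out1.read_bytes(), f"trial {trial} compressed"

        out_again = work / "out_again.vcf"
        stats = filter_file(out1, out_again, config)
        assert stats.records_kept == stats.records_read == len(got), (
            f"trial {trial} not idempotent"
        )
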
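"""Transfer plans, parameter copying, partitioned layers, phase training."""

import numpy as np
import pytest

from trigrec import datasets
from trigrec.config import TrainConfig
from trigrec.corpus_io import Corpus, LabelSet
from trigrec.errors import ConfigError, PlanError
from trigrec.features import FeatureConfig
from trigrec.models import train_basic
from trigrec.network import init_parameters
from trigrec.synthetic import SynthConfig, generate_domain_pair
from trigrec.transfer import (DomainSpec, SharedBlock, TransferModel,
                              TransferPlan, build_transfer_plan,
                              partitioned_middle_forward,
                              partitioned_output_forward, subsample_source,
                              transfer_parameters)

SFC = FeatureConfig(dim_word=8, dim_pos=3, dim_entity=3, dim_dep=4, use_char=False)
TFC = FeatureConfig(dim_word=8, dim_pos=3, dim_entity=5, dim_dep=4, use_char=False)


def _spec(name, labels, fconfig, dd=("entity",)):
    return DomainSpec(name, LabelSet(tuple(labels)), fconfig,
                      domain_dependent_channels=dd)


class TestBuildTransferPlan:
    def test_variant_a_is_empty(self):
        plan = build_transfer_plan(_spec("s", "XY", SFC), _spec("t", "PQ", TFC), "A")
        assert plan.is_empty()

    def test_d_reduces_to_b_with_identical_features_disjoint_labels(self):
        s = _spec("s", ("X", "Y"), SFC, dd=())
        t = _spec("t", ("P", "Q"), SFC, dd=())
        d = build_transfer_plan(s, t, "D")
        b = build_transfer_plan(s, t, "B")
        assert d.shared == b.shared
        assert not any(sb.block.startswith(("fc.", "proj.")) for sb in d.shared)
        assert any(sb.block == "lstm.f.W_h" for sb in d.shared)

    def test_d_reduces_to_c_with_different_features_disjoint_labels(self):
        s = _spec("s", ("X", "Y"), SFC)
        t = _spec("t", ("P", "Q"), TFC)
        d = build_transfer_plan(s, t, "D")
        c = build_transfer_plan(s, t, "C")
        assert d.shared == c.shared
        assert all(sb.block.startswith("emb.") for sb in d.shared)
        assert not any(sb.block == "emb.entity" for sb in d.shared)

    def test_c_shares_domain_independent_tables_only(self):
        plan = build_transfer_plan(_spec("s", "XY", SFC), _spec("t", "PQ", TFC), "C")
        names = set(plan.block_names())
        assert {"emb.word", "emb.pos", "emb.dep"} <= names
        assert "emb.entity" not in names and not any("lstm" in n for n in names)

    def test_b_with_inconsistent_features_is_plan_error(self):
        with pytest.raises(PlanError):
            build_transfer_plan(_spec("s", "XY", SFC), _spec("t", "PQ", TFC), "B")

    def test_reference_geometry_st09_to_mlee(self):
        """High-overlap pair: 9 shared projection rows; entity input rows
        stay specific while all other BiLSTM blocks are shared; nothing of
        the CRF is shared."""
        plan = build_transfer_plan(
            _spec("st09", datasets.ST09_TRIGGER_TYPES, FeatureConfig.source_default()),
            _spec("mlee", datasets.MLEE_TRIGGER_TYPES, FeatureConfig.target_default()),
            "D")
        by_name = {}
        for sb in plan.shared:
            by_name.setdefault(sb.block, sb)
        assert len(by_name["proj.W"].src_index) == 9
        assert len(by_name["proj.b"].src_index) == 9
        # input rows: everything except the 10-dim source entity channel
        assert len(by_name["lstm.f.W_x"].src_index) == 660 - 10
        assert len(by_name["lstm.f.W_x"].tgt_index) == 700 - 50
        for block in ("lstm.f.W_h", "lstm.b.W_h", "lstm.f.p_i", "fc.W", "fc.b"):
            assert by_name[block].src_index is None
        assert not any("crf" in n for n in by_name)

    def test_plan_json_roundtrip(self):
        plan = build_transfer_plan(
            _spec("s", datasets.ST09_TRIGGER_TYPES, SFC),
            _spec("t", datasets.MLEE_TRIGGER_TYPES, TFC), "D")
        assert TransferPlan.from_json(plan.to_json()) == plan

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            build_transfer_plan(_spec("s", "X", SFC), _spec("t", "Y", TFC), "E")


def _bundles(rng, tiny_pair):
    from trigrec.features import build_transfer_vocabs

    cfg, source, target, _ = tiny_pair
    sv, tv = build_transfer_vocabs(source, target)
    src = init_parameters(sv, SFC, LabelSet(cfg.source_labels).tags, 4, 6, rng)
    tgt = init_parameters(tv, TFC, LabelSet(cfg.target_labels).tags, 4, 6, rng)
    return cfg, src, tgt


class TestTransferParameters:
    def test_empty_plan_leaves_target_unchanged(self, rng, tiny_pair):
        _, src, tgt = _bundles(rng, tiny_pair)
        before = tgt.copy()
        audit = transfer_parameters(src, TransferPlan("A", ()), tgt)
        assert audit.copied == () and tgt.allclose(before)

    def test_all_shared_plan_copies_every_block(self, rng, tiny_pair):
        from trigrec.features import build_transfer_vocabs

        cfg, source, target, _ = tiny_pair
        sv, _ = build_transfer_vocabs(source, target)
        src = init_parameters(sv, SFC, LabelSet(cfg.source_labels).tags, 4, 6, rng)
        tgt = init_parameters(sv, SFC, LabelSet(cfg.source_labels).tags, 4, 6,
                              np.random.default_rng(99))
        plan = TransferPlan("D", tuple(SharedBlock(b) for b in src.blocks))
        audit = transfer_parameters(src, plan, tgt)
        assert tgt.allclose(src)
        assert audit.total_params == src.n_params()

    def test_idempotent_and_never_touches_crf_or_specific(self, rng, tiny_pair):
        cfg, src, tgt = _bundles(rng, tiny_pair)
        s = _spec("s", cfg.source_labels, SFC)
        t = _spec("t", cfg.target_labels, TFC)
        plan = build_transfer_plan(s, t, "D")
        crf_before = tgt.blocks["crf.trans"].copy()
        ent_before = tgt.blocks["emb.entity"].copy()
        transfer_parameters(src, plan, tgt)
        snapshot = tgt.copy()
        transfer_parameters(src, plan, tgt)
        assert tgt.allclose(snapshot)  # idempotent
        assert np.array_equal(tgt.blocks["crf.trans"], crf_before)
        assert np.array_equal(tgt.blocks["emb.entity"], ent_before)
        # unshared projection columns (target-only labels) keep their init
        by_name = {sb.block: sb for sb in plan.shared}
        shared_cols = set(by_name["proj.W"].tgt_index)
        spec_cols = [j for j in range(tgt.blocks["proj.W"].shape[1])
                     if j not in shared_cols]
        assert np.array_equal(tgt.blocks["proj.W"][:, spec_cols],
                              snapshot.blocks["proj.W"][:, spec_cols])

    def test_missing_block_raises(self, rng, tiny_pair):
        _, src, tgt = _bundles(rng, tiny_pair)
        plan = TransferPlan("D", (SharedBlock("nope.W"),))
        with pytest.raises(PlanError):
            transfer_parameters(src, plan, tgt)

    def test_shape_conflict_names_block(self, rng, tiny_pair):
        _, src, tgt = _bundles(rng, tiny_pair)
        plan = TransferPlan("D", (SharedBlock("emb.entity"),))
        with pytest.raises(PlanError, match="emb.entity"):
            transfer_parameters(src, plan, tgt)


class TestPartitionedLayers:
    def test_empty_specific_block_is_plain_dense(self, rng):
        x = rng.normal(size=4)
        W = rng.normal(size=(4, 3))
        b = rng.normal(size=3)
        out = partitioned_middle_forward(np.zeros(0), x, np.zeros((0, 3)), W, b)
        assert np.allclose(out, x @ W + b, atol=1e-12)

    def test_middle_partition_equals_dense_on_concatenation(self, rng):
        for _ in range(20):
            ds, dh, out_dim = rng.integers(1, 6, size=3)
            xs = rng.normal(size=ds)
            xh = rng.normal(size=dh)
            Ws = rng.normal(size=(ds, out_dim))
            Wh = rng.normal(size=(dh, out_dim))
            b = rng.normal(size=out_dim)
            got = partitioned_middle_forward(xs, xh, Ws, Wh, b,
                                             active_function=np.tanh)
            dense = np.tanh(np.concatenate([xs, xh]) @ np.vstack([Ws, Wh]) + b)
            assert np.allclose(got, dense, atol=1e-10)

    def test_middle_partition_permutation_invariant(self, rng):
        ds, dh, out_dim = 3, 4, 2
        xs, xh = rng.normal(size=ds), rng.normal(size=dh)
        Ws, Wh = rng.normal(size=(ds, out_dim)), rng.normal(size=(dh, out_dim))
        b = rng.normal(size=out_dim)
        base = partitioned_middle_forward(xs, xh, Ws, Wh, b)
        x = np.concatenate([xs, xh])
        W = np.vstack([Ws, Wh])
        perm = rng.permutation(ds + dh)
        permuted = partitioned_middle_forward(
            x[perm][:ds], x[perm][ds:], W[perm][:ds], W[perm][ds:], b)
        assert np.allclose(base, permuted, atol=1e-12)

    def test_output_partition_stacks_to_dense(self, rng):
        for _ in range(20):
            d = int(rng.integers(2, 6))
            tags = ["O", "A", "B"]
            x = rng.normal(size=d)
            rows = {t: (rng.normal(size=d), rng.normal()) for t in tags}
            shared = {t: rows[t] for t in ("A",)}
            specific = {t: rows[t] for t in ("O", "B")}
            got = partitioned_output_forward(x, shared, specific, tags)
            W = np.stack([rows[t][0] for t in tags], axis=1)
            b = np.array([rows[t][1] for t in tags])
            assert np.allclose(got, x @ W + b, atol=1e-10)

    def test_all_labels_shared_is_dense(self, rng):
        tags = ["A", "B"]
        x = rng.normal(size=3)
        shared = {t: (rng.normal(size=3), rng.normal()) for t in tags}
        got = partitioned_output_forward(x, shared, {}, tags)
        W = np.stack([shared[t][0] for t in tags], axis=1)
        assert np.allclose(got, x @ W + [shared[t][1] for t in tags], atol=1e-12)

    def test_empty_overlap_uses_only_specific_rows(self, rng):
        tags = ["A"]
        specific = {"A": (np.ones(2), 0.5)}
        got = partitioned_output_forward(np.ones(2), {}, specific, tags)
        assert got[0] == pytest.approx(2.5)

    def test_unpartitioned_label_rejected(self):
        with pytest.raises(ConfigError):
            partitioned_output_forward(np.ones(2), {}, {}, ["A"])

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ConfigError):
            partitioned_middle_forward(np.ones(2), np.ones(3),
                                       np.ones((5, 2)), np.ones((3, 2)),
                                       np.zeros(2))


class TestSubsample:
    def test_ratio_one_is_identity(self, tiny_pair):
        _, source, _, _ = tiny_pair
        sub = subsample_source(source, 1.0, seed=0)
        assert sub.documents == source.documents

    def test_ratio_zero_is_empty(self, tiny_pair):
        _, source, _, _ = tiny_pair
        assert subsample_source(source, 0.0, seed=0).n_documents == 0

    def test_floor_arithmetic_on_reference_size(self):
        corpus = Corpus("big", [[[]]] * 950)
        assert subsample_source(corpus, 0.8, seed=1).n_documents == 760

    def test_seeded_and_without_replacement(self, tiny_pair):
        _, source, _, _ = tiny_pair
        a = subsample_source(source, 0.5, seed=7)
        b = subsample_source(source, 0.5, seed=7)
        assert [id(d) for d in a.documents] == [id(d) for d in b.documents]
        assert len({id(d) for d in a.documents}) == a.n_documents


def _phase_setup(seed=9, epochs=3):
    cfg = SynthConfig(n_source_docs=6, n_target_docs=4, sentences_per_doc=3,
                      seed=seed, ambiguity=0.2)
    source, target, _ = generate_domain_pair(cfg)
    tc = TrainConfig(hidden_size=6, fc_size=8, learning_rate=0.02, batch_size=4,
                     epochs=epochs, dropout=0.3, early_stopping=False)
    s = _spec("s", cfg.source_labels, SFC)
    t = _spec("t", cfg.target_labels, TFC)
    return source, target, s, t, tc


class TestThreePhaseTraining:
    def test_no_transfer_run_matches_train_basic_bitwise(self):
        source, target, s, t, tc = _phase_setup()
        tc = tc.with_(source_ratio=0.0)
        res_t = TransferModel(source, target, s, t, variant="A",
                              train_config=tc).fit(seed=7)
        res_b = train_basic(target, t.label_set, TFC, tc, seed=7)
        for k in res_b.params.blocks:
            assert np.array_equal(res_t.params.blocks[k],
                                  res_b.params.blocks[k]), k

    def test_zero_ratio_with_transfer_plan_also_collapses_to_baseline(self):
        source, target, s, t, tc = _phase_setup()
        tc = tc.with_(source_ratio=0.0)
        res_t = TransferModel(source, target, s, t, variant="D",
                              train_config=tc).fit(seed=7)
        res_b = train_basic(target, t.label_set, TFC, tc, seed=7)
        for k in res_b.params.blocks:
            assert np.array_equal(res_t.params.blocks[k],
                                  res_b.params.blocks[k]), k

    def test_identity_transfer_with_frozen_phase3(self):
        """Identical domains, an all-shared plan and a frozen (0-epoch)
        phase 3: the target model must score exactly like the source model."""
        source, _, s, _, tc = _phase_setup(epochs=4)
        t_same = _spec("t", s.label_set.labels, SFC)
        tc = tc.with_(epochs=0, epochs_source=4, source_dev_fraction=0.0)
        tm = TransferModel(source, source, s, t_same, variant="D",
                           train_config=tc)
        src_results = tm.fit_source(seed=3)
        plan = TransferPlan("D", tuple(SharedBlock(b)
                                       for b in src_results.params.blocks))
        res = tm.fit_target(src_results, seed=3, plan=plan)
        assert res.params.allclose(src_results.params)
        assert res.evaluate(source).rounded() \
            == src_results.evaluate(source).rounded()

    def test_transfer_audit_covers_plan_and_skips_crf(self):
        source, target, s, t, tc = _phase_setup()
        res = TransferModel(source, target, s, t, variant="D",
                            train_config=tc).fit(seed=2)
        assert set(res.audit.block_names()) == set(res.plan.block_names())
        assert not any("crf" in b for b in res.audit.block_names())
        assert res.audit.total_params > 0

    def test_history_records_both_phases(self):
        source, target, s, t, tc = _phase_setup()
        res = TransferModel(source, target, s, t, variant="D",
                            train_config=tc).fit(seed=2)
        phases = {h["phase"] for h in res.history}
        assert phases == {"source", "target"}
        assert "loss" in res.history[0]

    def test_ratio_sweep_shape_contract(self):
        from trigrec.transfer import run_ratio_sweep

        source, target, s, t, tc = _phase_setup(epochs=1)
        dev = Corpus("target", target.documents[:2])
        train = Corpus("target", target.documents[2:])
        rows = run_ratio_sweep(source, train, dev, s, t,
                               ratios=[0.0, 1.0], seeds=[0, 1],
                               variant="D", train_config=tc)
        assert len(rows) == 2
        assert all(len(r["f1_per_seed"]) == 2 for r in rows)
        assert rows[0]["ratio"] == 0.0
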
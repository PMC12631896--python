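"""Fusion weights, weighted concatenation, total loss and transfer training."""

import numpy as np
import pytest

from fusebci.base_networks import FeatureBatch, build_base_model
from fusebci.fusion_training import (
    TransferRunConfig,
    build_fusion_model,
    evaluate_fusion_no_transfer,
    fuse_features,
    fusion_weights,
    select_sources,
    total_loss,
    train_transfer,
    _train_fusion_fold,
)
from fusebci.transfer_losses import LossBundle, TransferLossConfig


def test_fusion_weights_symmetry_and_substitution():
    w = fusion_weights(0.7, 0.7)
    assert w.a == w.b == pytest.approx(0.5)
    w = fusion_weights(0.75, 0.25)
    assert (w.a, w.b) == (pytest.approx(0.75), pytest.approx(0.25))


@pytest.mark.parametrize("ae,an", [(0.3, 0.9), (1.0, 0.01), (0.5, 0.5)])
def test_fusion_weights_normalize_to_one(ae, an):
    w = fusion_weights(ae, an)
    assert w.a + w.b == pytest.approx(1.0, rel=1e-12)
    assert 0 <= w.a <= 1 and 0 <= w.b <= 1


def test_fusion_weights_errors():
    with pytest.raises(ValueError, match="undefined"):
        fusion_weights(0.0, 0.0)
    with pytest.raises(ValueError, match="fractions"):
        fusion_weights(1.2, 0.5)


def test_fuse_features_weighted_concatenation(rng):
    fe = FeatureBatch(rng.standard_normal((4, 3)), "s")
    fn = FeatureBatch(rng.standard_normal((4, 2)), "s")
    fused = fuse_features(fe, fn, fusion_weights(0.75, 0.25))
    assert fused.values.shape == (4, 5)
    np.testing.assert_allclose(fused.values[:, :3], 0.75 * fe.values)
    np.testing.assert_allclose(fused.values[:, 3:], 0.25 * fn.values)


def test_fuse_features_boundary_weights_zero_one(rng):
    fe = FeatureBatch(rng.standard_normal((3, 2)), "s")
    fn = FeatureBatch(rng.standard_normal((3, 2)), "s")
    fused = fuse_features(fe, fn, fusion_weights(1.0, 0.0))
    np.testing.assert_allclose(fused.values[:, 2:], 0.0)
    np.testing.assert_allclose(fused.values[:, :2], fe.values)


def test_fuse_features_row_mismatch_raises(rng):
    fe = FeatureBatch(rng.standard_normal((3, 2)), "s")
    fn = FeatureBatch(rng.standard_normal((4, 2)), "s")
    with pytest.raises(ValueError, match="row mismatch"):
        fuse_features(fe, fn, fusion_weights(0.5, 0.5))


def test_total_loss_hand_example():
    bundle = LossBundle(l_clf=0.6931, l_dcca_eeg=-0.2, l_dcca_fnirs=0.1)
    w = fusion_weights(0.5, 0.5)
    assert total_loss(bundle, w) == pytest.approx(0.6431, rel=1e-12)
    zero = LossBundle(l_clf=0.42)
    assert total_loss(zero, w) == pytest.approx(0.42)
    assert LossBundle(l_clf=1.0, l_dcca_eeg=-0.5).total(1.0, 0.0) == pytest.approx(0.5)


def test_build_fusion_model_shapes_and_determinism(compact_specs, rng):
    eeg_ckpt = build_base_model(compact_specs["eeg"], seed=1)
    fnirs_ckpt = build_base_model(compact_specs["fnirs"], seed=2)
    w = fusion_weights(0.6, 0.4)
    model = build_fusion_model(eeg_ckpt, fnirs_ckpt, w, seed=0)
    xe = rng.standard_normal((2, compact_specs["eeg"].input_channels,
                              compact_specs["eeg"].input_samples))
    xn = rng.standard_normal((2, compact_specs["fnirs"].input_channels,
                              compact_specs["fnirs"].input_samples))
    logits, _ = model.forward(xe, xn, train=False)
    assert logits.shape == (2, 2)
    d = model.d_eeg + model.d_fnirs
    head = model.head.layers[0]
    assert head.params["W"].size + head.params["b"].size == d * 2 + 2
    again = build_fusion_model(eeg_ckpt, fnirs_ckpt, w, seed=0)
    np.testing.assert_array_equal(logits, again.forward(xe, xn, train=False)[0])


def test_fusion_model_checkpoint_mismatch_raises(compact_specs):
    eeg_ckpt = build_base_model(compact_specs["eeg"], seed=1)
    bad = build_base_model(compact_specs["eeg"], seed=1)
    # corrupt a parameter shape in the checkpoint source
    state = bad.feature_extractor.state_dict()
    key = next(iter(state))
    state[key] = np.zeros((1, 1))
    with pytest.raises(ValueError, match="checkpoint shape"):
        eeg_ckpt.feature_extractor.load_state_dict(state)


def test_select_sources_picks_roster_members(population6, pretrained6):
    sel = select_sources(population6, pretrained6)
    ids = {sd.subject_id for sd in population6}
    assert sel.eeg_source in ids and sel.fnirs_source in ids
    same = select_sources(population6, pretrained6, source_mode="same")
    assert same.eeg_source == same.fnirs_source


def test_transfer_run_config_validation():
    with pytest.raises(ValueError, match="source_mode"):
        TransferRunConfig(target="t", source_mode="mixed")
    with pytest.raises(ValueError, match="learning rate"):
        TransferRunConfig(target="t", lr=0.0)


def test_missing_pretrained_checkpoint_raises(population6, compact_specs):
    cfg = TransferRunConfig(target=population6[0].subject_id,
                            source_eeg="S99", source_fnirs="S99")
    with pytest.raises(KeyError, match="pretrain"):
        train_transfer(population6, cfg, {}, compact_specs)


def test_transfer_loss_identities_hold_during_training(population6, pretrained6,
                                                       compact_specs):
    """Every logged step satisfies a + b = 1 and the total-loss
    reconstruction from its components to 1e-6."""
    sel = select_sources(population6, pretrained6)
    target = next(sd for sd in population6
                  if sd.subject_id not in (sel.eeg_source, sel.fnirs_source))
    eeg_ckpt = pretrained6[(sel.eeg_source, "eeg")]
    fnirs_ckpt = pretrained6[(sel.fnirs_source, "fnirs")]
    w = fusion_weights(pretrained6[(target.subject_id, "eeg")].meta["val_accuracy"],
                       pretrained6[(target.subject_id, "fnirs")].meta["val_accuracy"])
    assert w.a + w.b == pytest.approx(1.0, rel=1e-12)
    model = build_fusion_model(eeg_ckpt, fnirs_ckpt, w, seed=0)
    cfg = TransferRunConfig(target=target.subject_id, epochs=2, seed=0,
                            loss=TransferLossConfig(arm="ours"))
    log = _train_fusion_fold(model, target.eeg, target.fnirs,
                             target.eeg, target.fnirs,
                             next(sd for sd in population6
                                  if sd.subject_id == sel.eeg_source).eeg,
                             next(sd for sd in population6
                                  if sd.subject_id == sel.fnirs_source).fnirs,
                             cfg)
    assert len(log) > 0
    for bundle in log:
        recon = (bundle.l_clf + w.a * bundle.l_trans_eeg
                 + w.b * bundle.l_trans_fnirs)
        assert total_loss(bundle, w) == pytest.approx(recon, abs=1e-6)
        assert np.isfinite(bundle.l_clf)


def test_zero_transfer_scale_logs_no_transfer_terms(population6, pretrained6,
                                                    compact_specs):
    sd = population6[0]
    w = fusion_weights(0.5, 0.5)
    model = build_fusion_model(build_base_model(compact_specs["eeg"], seed=0),
                               build_base_model(compact_specs["fnirs"], seed=1),
                               w, seed=0)
    cfg = TransferRunConfig(target=sd.subject_id, epochs=1,
                            transfer_weight_scale=0.0, seed=0)
    log = _train_fusion_fold(model, sd.eeg, sd.fnirs, sd.eeg, sd.fnirs,
                             None, None, cfg)
    assert all(b.l_trans_eeg == 0.0 and b.l_trans_fnirs == 0.0 for b in log)


def test_source_initialization_differs_from_random_init(population6, pretrained6,
                                                        compact_specs):
    """Extractors initialized from a source checkpoint behave differently
    from random initialization from the very first forward pass."""
    sel = select_sources(population6, pretrained6)
    target = next(sd for sd in population6
                  if sd.subject_id not in (sel.eeg_source, sel.fnirs_source))
    w = fusion_weights(0.5, 0.5)
    src = build_fusion_model(pretrained6[(sel.eeg_source, "eeg")],
                             pretrained6[(sel.fnirs_source, "fnirs")], w, seed=0)
    rnd = build_fusion_model(build_base_model(compact_specs["eeg"], seed=123),
                             build_base_model(compact_specs["fnirs"], seed=124),
                             w, seed=0)
    a, _ = src.forward(target.eeg.data[:4], target.fnirs.data[:4], train=False)
    b, _ = rnd.forward(target.eeg.data[:4], target.fnirs.data[:4], train=False)
    assert not np.allclose(a, b)


def test_train_transfer_smoke_and_report(population6, pretrained6, compact_specs):
    sel = select_sources(population6, pretrained6)
    target = next(sd for sd in population6
                  if sd.subject_id not in (sel.eeg_source, sel.fnirs_source))
    lab = np.arange(20)
    cfg = TransferRunConfig(target=target.subject_id, source_eeg=sel.eeg_source,
                            source_fnirs=sel.fnirs_source, epochs=5, seed=0)
    model, report = train_transfer(population6, cfg, pretrained6, compact_specs,
                                   labeled_idx=lab)
    assert report.n_evaluated == 40
    assert 0.0 <= report.accuracy <= 1.0
    assert report.confusion_matrix.sum() == 40
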
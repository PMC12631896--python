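"""Reproducible scaled-down studies run by the acceptance checks and CLI.

These orchestrate the full pipeline — synthetic population, per-subject
pretraining, trusted-score source selection, fusion transfer training —
at the compact study scale (8-channel EEG at 50 Hz, 12-channel fNIRS,
6 subjects) so a complete cross-subject experiment runs in minutes on one
CPU.  The scientific content (paradigm timing, 60 trials per subject,
planted ERD/hemodynamics) is unchanged from the full-scale generator.
"""

from __future__ import annotations

import numpy as np

from .base_networks import NetworkSpec
from .data_model import SubjectDataset
from .fusion_training import (
    TransferRunConfig,
    pretrain_population,
    select_sources,
    train_transfer,
)
from .synthetic_data import (
    GenParams,
    PopulationSpec,
    SubjectProfile,
    estimate_erd_ratio,
    generate_subject,
)
from .transfer_losses import TransferLossConfig

__all__ = [
    "compact_specs",
    "build_compact_population",
    "erd_recovery_errors",
    "null_pipeline_accuracy",
    "transfer_gain_study",
]


def compact_specs() -> dict[str, NetworkSpec]:
    return {"eeg": NetworkSpec.eeg_compact(), "fnirs": NetworkSpec.fnirs_compact()}


def build_compact_population(n_subjects: int = 6, master_seed: int = 5,
                             fraction_patient: float = 0.0):
    from .synthetic_data import generate_population

    spec = PopulationSpec(n_subjects=n_subjects, gen_params=GenParams.compact(),
                          master_seed=master_seed,
                          fraction_patient=fraction_patient)
    return generate_population(spec)


def erd_recovery_errors(depths=(0.0, 0.25, 0.5, 0.75), seed: int = 7):
    """|estimated alpha power ratio - (1 - depth)^2| per planted depth."""
    errors = {}
    for depth in depths:
        sd = generate_subject(SubjectProfile(erd_depth=depth),
                              gp=GenParams.compact(), seed=seed,
                              subject_id=f"D{depth}")
        ratio = estimate_erd_ratio(sd, hand="left")
        errors[depth] = abs(ratio - (1.0 - depth) ** 2)
    return errors


def null_pipeline_accuracy(seed: int = 0, epochs: int = 15) -> tuple[float, int]:
    """5-fold accuracy of the fusion pipeline on a subject with the planted
    signal switched off (ERD depth 0, hemodynamic gain 0).

    Type-I control of the whole stack: with no class-dependent signal the
    decoder must stay at chance.  Returns (pooled accuracy fraction,
    number of evaluated trials).
    """
    from .evaluation import evaluate_method

    sd = generate_subject(SubjectProfile(erd_depth=0.0, hemo_gain=0.0),
                          gp=GenParams.compact(), seed=seed + 101,
                          subject_id="NULL")
    reports, _ = evaluate_method([sd], "linear_fusion_no_transfer",
                                 specs=compact_specs(),
                                 transfer_epochs=epochs, seed=seed)
    rep = reports["NULL"]
    return rep.pooled_accuracy, rep.n_evaluated


def transfer_gain_study(population: list[SubjectDataset], pretrained: dict,
                        specs: dict, n_runs: int = 10, n_labeled: int = 20,
                        epochs: int = 15, seed: int = 0):
    """Full method vs no-transfer baseline with few labeled target trials.

    Sources are the trusted-score optima (separate per modality); each run
    picks a target among the remaining subjects, draws a stratified set of
    ``n_labeled`` labeled trials, trains (a) the source-initialized fusion
    model with DCCA+CORAL transfer and (b) the random-initialized fusion
    model with cross-entropy only, and scores both on the held-out trials.
    Returns a dict of per-run accuracy arrays.
    """
    sel = select_sources(population, pretrained, source_mode="separate")
    targets = [sd for sd in population
               if sd.subject_id not in (sel.eeg_source, sel.fnirs_source)]
    ours, baseline = [], []
    for run in range(n_runs):
        target = targets[run % len(targets)]
        run_seed = (seed + 7919 * (run + 1)) % (2**31)
        rng = np.random.default_rng(run_seed)
        labeled = np.sort(np.concatenate([
            rng.permutation(np.flatnonzero(target.eeg.labels == c))[: n_labeled // 2]
            for c in (0, 1)
        ]))
        cfg = TransferRunConfig(
            target=target.subject_id, source_eeg=sel.eeg_source,
            source_fnirs=sel.fnirs_source, epochs=epochs, seed=run_seed,
            loss=TransferLossConfig(arm="ours"))
        _, rep = train_transfer(population, cfg, pretrained, specs,
                                labeled_idx=labeled)
        ours.append(rep.pooled_accuracy)
        cfg0 = TransferRunConfig(target=target.subject_id, epochs=epochs,
                                 seed=run_seed, transfer_weight_scale=0.0)
        _, rep0 = train_transfer(population, cfg0, pretrained, specs,
                                 labeled_idx=labeled)
        baseline.append(rep0.pooled_accuracy)
    return {
        "ours": np.array(ours),
        "no_transfer": np.array(baseline),
        "eeg_source": sel.eeg_source,
        "fnirs_source": sel.fnirs_source,
        "n_labeled": n_labeled,
        "n_runs": n_runs,
    }
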
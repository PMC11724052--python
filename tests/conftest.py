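"""Shared fixtures: one pore model, one trained classifier, and simulated
benchmark samples reused across the suite (simulation and training dominate
test runtime, so they are session-scoped)."""

import pytest

import tailcomp as tc
from tailcomp import detect as D

MODEL_SEED = 7
BENCH_N_READS = 500


@pytest.fixture(scope="session")
def model():
    return tc.build_pore_model(k=5, seed=MODEL_SEED)


@pytest.fixture(scope="session")
def classifier(model):
    windows = D.make_training_windows(model, n_per_class=120, noise_sd=2.0,
                                      seed=5)
    return D.train_classifier(windows, seed=5, a_level=model.a_level)


def _make_sample(model, noise_sd, seed, n_reads=BENCH_N_READS, **kwargs):
    config = tc.SampleConfig(name=f"s{seed}", n_reads=n_reads,
                             noise_sd=noise_sd, **kwargs)
    reads, truth_reads, truth_residues, transcripts = tc.simulate_sample(
        config, model, seed=seed, return_transcripts=True)
    segmentations = [
        tc.segment_signal(r.signal, model, read_id=r.read_id,
                          transcript_nt=r.transcript_length_nt,
                          transcript_seq=transcripts[r.transcript_id],
                          contig=r.transcript_id)
        for r in reads
    ]
    return {
        "config": config,
        "reads": reads,
        "truth_reads": truth_reads,
        "truth_residues": truth_residues,
        "transcripts": transcripts,
        "segmentations": segmentations,
        "signals": {r.read_id: r.signal for r in reads},
    }


@pytest.fixture(scope="session")
def bench_sample(model):
    """Default-noise benchmark sample with segmentations."""
    return _make_sample(model, noise_sd=2.0, seed=11)


@pytest.fixture(scope="session")
def clean_sample(model):
    """Noise-free sample with segmentations (oracle comparisons)."""
    return _make_sample(model, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def bench_detection(model, classifier, bench_sample):
    class_data, residue_data = D.run_detection(
        bench_sample["signals"], bench_sample["segmentations"], classifier,
        model)
    return class_data, residue_data


@pytest.fixture(scope="session")
def clean_detection(model, classifier, clean_sample):
    class_data, residue_data = D.run_detection(
        clean_sample["signals"], clean_sample["segmentations"], classifier,
        model)
    return class_data, residue_data


@pytest.fixture(scope="session")
def adversarial_segmentations(model):
    suite = tc.simulate_adversarial_suite(model, seed=2)
    segs = {}
    for condition, read in suite:
        nt = read.transcript_length_nt or None
        segs[condition] = tc.segment_signal(
            read.signal, model, read_id=read.read_id, transcript_nt=nt)
    return segs
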
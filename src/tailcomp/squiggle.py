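"""Synthetic nanopore direct-RNA-sequencing (DRS) current traces with ground truth.

DRS reads a native RNA 3'->5', so the recorded squiggle starts with the
sequencing adapter, continues through the poly(A) tail (3'-terminal
nucleotide first) and ends with the transcript body.  This module generates
such traces from a synthetic pore model together with complete ground truth
(segment boundaries in samples, tail length in nucleotides, planted
non-adenosine residues and their positions), so that segmentation,
residue detection and all downstream statistics can be benchmarked without
any external sequencing data.

Conventions used throughout the package
---------------------------------------
* sample coordinates are 0-based, half-open intervals;
* tail positions are 1-based distances from the 3' terminus
  (position 1 = the 3'-terminal nucleotide, the first tail nucleotide to
  enter the pore);
* the emitted base order is adapter, tail (position 1, 2, ...), transcript
  body 3'->5'.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("tailcomp")

BASES = "ACGU"

#: Fixed synthetic 3' sequencing adapter (ligated downstream of the tail,
#: hence read first).  Ends in a non-A base so the adapter/tail junction is
#: a sharp level change; the segmenter uses its terminal k-mers as an
#: anchor.  The terminal base is G (the rarest tail residue class) because
#: the final junction k-mer G+AAAA is physically indistinguishable from a
#: guanosine at the very 3' end of the tail.
ADAPTER_SEQ = "GGCUUCUUCUUGCUCUUAGGUAGUAGCUUG"

#: Baseline current (pA) of the all-A pore state; only level *contrasts*
#: relative to this matter to the method.
A_STATE_LEVEL = 90.0

DEFAULT_SAMPLE_RATE = 3012.0
DEFAULT_TRANSLOCATION_RATE = 30.0
DEFAULT_NOISE_SD = 2.0
DEFAULT_SEPARATION = 10.0


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


# ---------------------------------------------------------------------------
# Pore model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoreModel:
    """Per-k-mer expected current level and spread.

    The table is synthetic: levels are drawn deterministically from a seed,
    with the constraint that every single-substitution neighbour of the
    all-A k-mer is separated from the all-A level by at least ``separation``
    pA.  Each non-A base perturbs the level with a characteristic signed
    magnitude (C up, G down, U up twice as far), which is what makes the
    three anomaly shapes distinguishable downstream.
    """

    k: int
    table: dict[str, tuple[float, float]]
    sample_rate: float = DEFAULT_SAMPLE_RATE
    translocation_rate: float = DEFAULT_TRANSLOCATION_RATE

    def level(self, kmer: str) -> float:
        return self.table[kmer][0]

    def sd(self, kmer: str) -> float:
        return self.table[kmer][1]

    @property
    def a_level(self) -> float:
        """Expected level of the all-A pore state (the poly(A) plateau)."""
        return self.level("A" * self.k)

    def adapter_anchor_level(self) -> float:
        """Level of the last pure-adapter k-mer, used as a segmentation anchor."""
        return self.level(ADAPTER_SEQ[-self.k:])

    def junction_levels(self) -> list[float]:
        """Expected levels of the k-1 adapter/tail junction k-mers, in signal order."""
        out = []
        for j in range(self.k - 1, 0, -1):
            kmer = ADAPTER_SEQ[-j:] + "A" * (self.k - j)
            out.append(self.level(kmer))
        return out


def _pick_weights(k: int, rng: np.random.Generator, separation: float) -> np.ndarray:
    """Choose per-position context weights for the pore model.

    Weights are a seeded permutation of k evenly spaced multipliers in
    [1.0, 1.4].  The narrow multiplier range keeps the three residue
    classes in disjoint amplitude bands (C in +[2.5, 3.5]*separation, G
    mirrored below, U in +[5, 7]*separation), so classes never collide at
    any context position; the permutation is chosen so the expected
    adapter junction/anchor event levels stay at least 0.5*separation away
    from every single-substitution level (the segmenter's junction model
    must never alias a genuine 3'-terminal residue anomaly).
    """
    base = np.linspace(1.0, 1.4, k)
    effects = np.array([2.5 * separation, -2.5 * separation, 5.0 * separation])  # C, G, U

    def junction_ok(w: np.ndarray) -> bool:
        eff = {"A": 0.0, "C": 2.5 * separation, "G": -2.5 * separation,
               "U": 5.0 * separation}
        singles = [e * wj for e in effects for wj in w]
        probes = []
        for m in range(k, 1, -1):  # anchor (m=k) and junction events m=k-1..2
            kmer = (ADAPTER_SEQ[-m:] + "A" * k)[:k]
            probes.append(sum(eff[b] * wj for b, wj in zip(kmer, w)))
        margin = 0.5 * separation
        return all(abs(p - s) >= margin for p in probes for s in singles)

    perms = [np.array(p) for p in itertools.permutations(range(k))]
    order = rng.permutation(len(perms))
    fallback = base[perms[order[0]]]
    for idx in order:
        w = base[perms[idx]]
        if junction_ok(w):
            return w
        fallback = w
    logger.warning("no context-weight permutation satisfies the junction "
                   "separation margin; using the last candidate")
    return fallback


def build_pore_model(
    k: int = 5,
    seed: int = 0,
    separation: float = DEFAULT_SEPARATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    translocation_rate: float = DEFAULT_TRANSLOCATION_RATE,
) -> PoreModel:
    """Build a deterministic synthetic pore model.

    Levels are ``A_STATE_LEVEL + sum_i effect(base_i) * w_i + eps(kmer)``
    where the per-position context weights ``w_i`` are a seeded permutation
    of k evenly spaced multipliers in [0.5, 1.5] (see ``_pick_weights``),
    the base effects are 0 (A), +2.5*separation (C), -2.5*separation (G)
    and +5*separation (U), and ``eps`` is a small per-k-mer jitter within
    +-0.1*separation.  By construction every single-substitution neighbour
    of the all-A k-mer differs from it by at least
    2.5*0.5*separation - 0.2*separation > separation.
    """
    if k not in (3, 4, 5, 6):
        raise ParameterError(f"k must be one of 3,4,5,6, got {k}")
    if separation <= 0:
        raise ParameterError("separation must be > 0")
    if translocation_rate <= 0:
        raise ParameterError("translocation_rate must be > 0")

    rng = np.random.default_rng(seed)
    weights = _pick_weights(k, rng, separation)
    effect = {"A": 0.0, "C": 2.5 * separation, "G": -2.5 * separation,
              "U": 5.0 * separation}

    table: dict[str, tuple[float, float]] = {}
    for kmer_tuple in itertools.product(BASES, repeat=k):
        kmer = "".join(kmer_tuple)
        eps = rng.uniform(-0.1, 0.1) * separation
        mean = A_STATE_LEVEL + sum(effect[b] * w for b, w in zip(kmer, weights)) + eps
        sd = rng.uniform(1.5, 3.0)
        table[kmer] = (float(mean), float(sd))

    model = PoreModel(k=k, table=table, sample_rate=sample_rate,
                      translocation_rate=translocation_rate)
    # construction guarantees the separation invariant; verify defensively
    a_mean = model.a_level
    for pos in range(k):
        for b in "CGU":
            neighbour = "A" * pos + b + "A" * (k - pos - 1)
            assert abs(model.level(neighbour) - a_mean) >= separation
    return model


# ---------------------------------------------------------------------------
# Read-level types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TailSpec:
    """Ground-truth description of one poly(A) tail.

    ``residues`` lists planted non-A nucleotides as
    ``(position_from_3prime, base)`` with 1-based positions.
    """

    tail_length_nt: int
    residues: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if self.tail_length_nt < 0:
            raise ParameterError("tail_length_nt must be >= 0")
        positions = [p for p, _ in self.residues]
        if len(set(positions)) != len(positions):
            raise ParameterError("residue positions must be unique")
        for pos, base in self.residues:
            if not (1 <= pos <= self.tail_length_nt):
                raise ParameterError(
                    f"residue position {pos} outside tail of length {self.tail_length_nt}")
            if base not in "CGU":
                raise ParameterError(f"residue base must be C, G or U, got {base!r}")

    def tail_sequence(self) -> str:
        """Tail bases in signal (3'->5') order: index 0 is position 1."""
        seq = ["A"] * self.tail_length_nt
        for pos, base in self.residues:
            seq[pos - 1] = base
        return "".join(seq)


@dataclass
class SyntheticRead:
    """A simulated squiggle plus full ground truth."""

    read_id: str
    transcript_id: str
    signal: np.ndarray
    sample_rate: float
    #: (adapter_start, polya_start, transcript_start, transcript_end), half-open
    truth_boundaries: tuple[int, int, int, int]
    truth_tail: TailSpec
    #: dwell (samples) of each tail nucleotide, position 1 first
    per_nt_dwell: np.ndarray
    transcript_length_nt: int = 0


def simulate_read(
    transcript_seq: str,
    tail_spec: TailSpec,
    model: PoreModel,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    read_id: str = "read_0",
    transcript_id: str = "tx_0",
) -> SyntheticRead:
    """Simulate one DRS read.

    One current event is emitted per k-mer of the emitted base sequence
    (adapter + tail + reversed transcript body); dwell times are i.i.d.
    geometric with mean ``model.translocation_rate`` and i.i.d. Gaussian
    noise of ``noise_sd`` pA is added per sample.  Event ``i`` is assigned
    to the segment of its first base, so the poly(A) segment covers exactly
    one event per tail nucleotide.  For truth boundaries to be exact at
    zero noise the transcript's 3' end should consist of A's for the last
    k-1 nucleotides (``random_transcript`` guarantees this).
    """
    if not transcript_seq:
        raise ParameterError("transcript sequence must be non-empty")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    transcript_seq = transcript_seq.upper().replace("T", "U")
    if set(transcript_seq) - set(BASES):
        raise ParameterError("transcript sequence must be over A/C/G/U (or T)")

    k = model.k
    n_adapter = len(ADAPTER_SEQ)
    tail_len = tail_spec.tail_length_nt
    emitted = ADAPTER_SEQ + tail_spec.tail_sequence() + transcript_seq[::-1]
    n_events = len(emitted) - k + 1
    if n_events <= n_adapter + tail_len:
        raise ParameterError("transcript too short for the k-mer window")

    rng = np.random.default_rng(seed)
    dwells = rng.geometric(1.0 / model.translocation_rate, size=n_events)
    levels = np.array([model.level(emitted[i:i + k]) for i in range(n_events)])

    signal = np.repeat(levels, dwells).astype(np.float64)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)

    csum = np.concatenate([[0], np.cumsum(dwells)])
    polya_start = int(csum[n_adapter])
    transcript_start = int(csum[n_adapter + tail_len])
    boundaries = (0, polya_start, transcript_start, int(csum[-1]))
    per_nt_dwell = dwells[n_adapter:n_adapter + tail_len].copy()

    return SyntheticRead(
        read_id=read_id,
        transcript_id=transcript_id,
        signal=signal,
        sample_rate=model.sample_rate,
        truth_boundaries=boundaries,
        truth_tail=tail_spec,
        per_nt_dwell=per_nt_dwell,
        transcript_length_nt=len(transcript_seq),
    )


# ---------------------------------------------------------------------------
# Sample-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleConfig:
    """Configuration of one simulated DRS sample.

    Defaults describe a testis-like condition: a minority of reads carry
    non-A residues, the residue mix is U > C >= G, and uridines are biased
    towards the 3' terminus of the tail.
    """

    name: str = "sample"
    n_reads: int = 2000
    tail_length_range: tuple[int, int] = (20, 250)
    decorated_fraction: float = 0.1
    residue_weights: dict[str, float] = field(
        default_factory=lambda: {"C": 0.25, "G": 0.15, "U": 0.60})
    terminal_bias: float = 0.7
    max_residues_per_read: int = 3
    #: the 3'-terminal-most plantable position; position 1's k-mer context
    #: overlaps the ligated adapter and is not resolvable in signal space
    min_residue_position: int = 2
    noise_sd: float = DEFAULT_NOISE_SD
    n_transcripts: int = 20
    transcript_length_range: tuple[int, int] = (300, 500)

    def __post_init__(self):
        if not (0.0 <= self.decorated_fraction <= 1.0):
            raise ParameterError("decorated_fraction must be in [0, 1]")
        if not (0.0 <= self.terminal_bias <= 1.0):
            raise ParameterError("terminal_bias must be in [0, 1]")
        total = sum(self.residue_weights.values())
        if abs(total - 1.0) > 1e-9:
            logger.warning("residue weights sum to %.4f; normalizing", total)
            self.residue_weights = {b: w / total for b, w in self.residue_weights.items()}


def random_transcript(length: int, rng: np.random.Generator, k: int = 5) -> str:
    """Random transcript body whose 3'-terminal k-1 nt are A.

    Annotated transcript 3' ends abut the poly(A) tail; padding the
    junction with exactly k-1 adenosines keeps the tail/body boundary
    sharp in k-mer space.  The body itself must not contain an adenosine
    homopolymer of length k: such a stretch would recreate the poly(A)
    pore state inside the transcript, making the tail boundary (and hence
    the ground truth of this generator) ill-defined.
    """
    n_core = max(1, length - (k - 1))
    for _ in range(100):
        core = "".join(rng.choice(list(BASES), size=n_core))
        if "A" * k not in core + "A" * (k - 1):
            return core + "A" * (k - 1)
    # extraordinarily unlikely; break the run explicitly
    core = core.replace("A" * k, "A" * (k - 1) + "C")
    return core[:n_core - 1].ljust(n_core, "C") + "A" * (k - 1)


def _draw_residues(
    rng: np.random.Generator,
    tail_len: int,
    n_residues: int,
    weights: dict[str, float],
    terminal_bias: float,
    k: int,
    min_pos: int = 2,
) -> tuple[tuple[int, str], ...]:
    """Draw residue positions/bases for one decorated read.

    Positions are kept >= 3k apart, away from the tail's 5' junction
    (position <= tail_len - (k-1)) and at least ``min_pos`` from the 3'
    end, so every planted residue is resolvable as a distinct
    k-mer-scale anomaly even under the dwell-time jitter of the
    translocation clock.
    """
    max_pos = max(min_pos, tail_len - (k - 1))
    terminal_zone = max(min_pos, tail_len // 10)
    bases = list(weights)
    probs = np.array([weights[b] for b in bases])
    chosen: list[int] = []
    for _ in range(40):  # rejection sampling with a cap
        if len(chosen) >= n_residues:
            break
        if rng.random() < terminal_bias:
            pos = int(rng.integers(min_pos, min(terminal_zone, max_pos) + 1))
        else:
            pos = int(rng.integers(min_pos, max_pos + 1))
        if all(abs(pos - q) >= 3 * k for q in chosen):
            chosen.append(pos)
    return tuple(sorted(
        (pos, str(rng.choice(bases, p=probs))) for pos in chosen))


def simulate_sample(config: SampleConfig, model: PoreModel, seed: int = 0,
                    return_transcripts: bool = False):
    """Simulate a whole sample.

    Returns ``(reads, truth_reads, truth_residues)`` where the truth tables
    are pandas DataFrames matching ``truth_reads.tsv`` / ``truth_residues.tsv``;
    with ``return_transcripts=True`` the reference sequences are appended as
    a fourth element.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    k = model.k

    tx_lengths = rng.integers(config.transcript_length_range[0],
                              config.transcript_length_range[1] + 1,
                              size=config.n_transcripts)
    transcripts = {
        f"tx_{i:04d}": random_transcript(int(L), rng, k=k)
        for i, L in enumerate(tx_lengths)
    }
    tx_ids = list(transcripts)
    # log-normal abundance weights give realistic spread for concordance stats
    abundance = rng.lognormal(0.0, 1.0, size=len(tx_ids))
    abundance /= abundance.sum()

    reads: list[SyntheticRead] = []
    read_rows = []
    residue_rows = []
    for i in range(config.n_reads):
        tx_id = tx_ids[rng.choice(len(tx_ids), p=abundance)]
        tail_len = int(rng.integers(config.tail_length_range[0],
                                    config.tail_length_range[1] + 1))
        decorated = rng.random() < config.decorated_fraction
        residues: tuple[tuple[int, str], ...] = ()
        if decorated:
            n_res = int(rng.integers(1, config.max_residues_per_read + 1))
            residues = _draw_residues(rng, tail_len, n_res,
                                      config.residue_weights,
                                      config.terminal_bias, k,
                                      min_pos=config.min_residue_position)
        spec = TailSpec(tail_length_nt=tail_len, residues=residues)
        read = simulate_read(
            transcripts[tx_id], spec, model,
            noise_sd=config.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            read_id=f"{config.name}_read_{i:05d}",
            transcript_id=tx_id,
        )
        reads.append(read)
        read_rows.append({
            "read_id": read.read_id,
            "transcript_id": tx_id,
            "tail_length_nt": tail_len,
            "n_residues": len(residues),
            "truth_class": "decorated" if residues else "blank",
        })
        for pos, base in residues:
            residue_rows.append({
                "read_id": read.read_id,
                "transcript_id": tx_id,
                "base": base,
                "position_nt": pos,
                "tail_length_nt": tail_len,
            })

    truth_reads = pd.DataFrame(read_rows)
    truth_residues = pd.DataFrame(
        residue_rows,
        columns=["read_id", "transcript_id", "base", "position_nt", "tail_length_nt"])
    if return_transcripts:
        return reads, truth_reads, truth_residues, transcripts
    return reads, truth_reads, truth_residues


# ---------------------------------------------------------------------------
# Adversarial reads for QC-tag coverage
# ---------------------------------------------------------------------------

def simulate_adversarial_suite(model: PoreModel, seed: int = 0,
                               noise_sd: float = DEFAULT_NOISE_SD):
    """Reads engineered to exercise every segmentation failure mode.

    Returns a list of ``(expected_condition, SyntheticRead)`` pairs with
    conditions: clean, truncated_transcript, missing_adapter, pure_noise,
    nan_signal.
    """
    rng = np.random.default_rng(seed)
    k = model.k
    suite = []

    tx = random_transcript(400, rng, k=k)
    clean = simulate_read(tx, TailSpec(100), model, noise_sd, seed=seed + 1,
                          read_id="adv_clean")
    suite.append(("clean", clean))

    short_tx = random_transcript(30, rng, k=k)
    trunc = simulate_read(short_tx, TailSpec(100), model, noise_sd, seed=seed + 2,
                          read_id="adv_truncated")
    suite.append(("truncated_transcript", trunc))

    noadapt = simulate_read(tx, TailSpec(100), model, noise_sd, seed=seed + 3,
                            read_id="adv_noadapter")
    ps = noadapt.truth_boundaries[1]
    sig = noadapt.signal[ps:].copy()
    a, b, c, d = noadapt.truth_boundaries
    noadapt = replace_boundaries(noadapt, sig, (0, 0, c - ps, d - ps))
    suite.append(("missing_adapter", noadapt))

    noise_sig = rng.normal(A_STATE_LEVEL, 25.0, size=8000)
    noise_read = SyntheticRead(
        read_id="adv_noise", transcript_id="none", signal=noise_sig,
        sample_rate=model.sample_rate, truth_boundaries=(0, 0, 0, len(noise_sig)),
        truth_tail=TailSpec(0), per_nt_dwell=np.array([], dtype=int))
    suite.append(("pure_noise", noise_read))

    nan_sig = clean.signal.copy()
    nan_sig[100:200] = np.nan
    nan_read = SyntheticRead(
        read_id="adv_nan", transcript_id="none", signal=nan_sig,
        sample_rate=model.sample_rate, truth_boundaries=clean.truth_boundaries,
        truth_tail=clean.truth_tail, per_nt_dwell=clean.per_nt_dwell)
    suite.append(("nan_signal", nan_read))

    return suite


def replace_boundaries(read: SyntheticRead, signal: np.ndarray,
                       boundaries: tuple[int, int, int, int]) -> SyntheticRead:
    return SyntheticRead(
        read_id=read.read_id, transcript_id=read.transcript_id, signal=signal,
        sample_rate=read.sample_rate, truth_boundaries=boundaries,
        truth_tail=read.truth_tail, per_nt_dwell=read.per_nt_dwell,
        transcript_length_nt=read.transcript_length_nt)


# ---------------------------------------------------------------------------
# On-disk sample container (text only)
# ---------------------------------------------------------------------------

def write_sample(directory, reads, truth_reads, truth_residues,
                 transcripts: dict[str, str] | None = None,
                 signal_decimals: int = 2) -> None:
    """Write a sample directory: signals.tsv, alignments.tsv, truth tables,
    and reads.fasta when transcript sequences are given.

    ``signals.tsv`` holds one read per row: read_id, sample_rate and the
    whitespace-separated samples on one line. ``alignments.tsv`` records the
    read-to-transcript assignment (the stand-in for the alignment stage,
    which is outside this package's scope).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "signals.tsv", "w") as fh:
        fh.write("read_id\tsample_rate\tsamples\n")
        for read in reads:
            samples = " ".join(
                format(x, f".{signal_decimals}f") for x in read.signal)
            fh.write(f"{read.read_id}\t{read.sample_rate:g}\t{samples}\n")

    with open(directory / "alignments.tsv", "w") as fh:
        fh.write("read_id\ttranscript_id\n")
        for read in reads:
            fh.write(f"{read.read_id}\t{read.transcript_id}\n")

    truth_reads.to_csv(directory / "truth_reads.tsv", sep="\t", index=False)
    truth_residues.to_csv(directory / "truth_residues.tsv", sep="\t", index=False)

    if transcripts:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        records = [SeqRecord(Seq(seq), id=tx_id, description="")
                   for tx_id, seq in transcripts.items()]
        SeqIO.write(records, directory / "reads.fasta", "fasta")


def read_sample(directory):
    """Read a sample directory written by :func:`write_sample`.

    Returns ``(signals, sample_rates, alignments, truth_reads, truth_residues)``
    where ``signals`` maps read_id to a float array and ``alignments`` maps
    read_id to transcript_id (empty when absent).
    """
    import pandas as pd

    directory = Path(directory)
    signals: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    with open(directory / "signals.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["read_id", "sample_rate"]:
            raise ValueError("signals.tsv must start with read_id, sample_rate columns")
        for line in fh:
            read_id, rate, samples = line.rstrip("\n").split("\t", 2)
            signals[read_id] = np.array(samples.split(), dtype=float)
            rates[read_id] = float(rate)

    alignments: dict[str, str] = {}
    aln_path = directory / "alignments.tsv"
    if aln_path.exists():
        aln = pd.read_csv(aln_path, sep="\t")
        alignments = dict(zip(aln["read_id"], aln["transcript_id"]))

    def _maybe(name):
        p = directory / name
        return pd.read_csv(p, sep="\t") if p.exists() else None

    return signals, rates, alignments, _maybe("truth_reads.tsv"), _maybe("truth_residues.tsv")


def read_fasta(path) -> dict[str, str]:
    """Reference transcript sequences keyed by id."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
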
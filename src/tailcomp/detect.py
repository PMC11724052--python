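"""Detection and classification of non-adenosine residues inside poly(A) tails.

A C, G or U embedded in the tail changes the current for the k consecutive
k-mer events that overlap it, leaving a characteristic local anomaly in the
otherwise flat poly(A) plateau.  Detection proceeds in three stages:

1. *moves* — significant level changes between consecutive windows of one
   translocation step each, thresholded at ``tau`` robust scales;
2. *anomaly gating* — moves are clustered into candidate excursions; a
   fixed-length window centred on each excursion must deviate from the
   all-A level by at least three robust scales and pass saturation sanity
   checks;
3. *classification* — each accepted window is encoded as a Gramian angular
   summation field (GASF) and assigned to C, G or U by a multinomial
   logistic classifier trained on simulated windows.

Every read receives exactly one of five classes: ``decorated`` (at least
one accepted residue call), ``blank`` (analysable tail, no moves),
``move_issue`` (moves but no window passes the anomaly gate),
``signal_issue`` (tail unanalysable or a gated window fails sanity checks)
and ``qc_failed`` (segmentation tag outside PASS/SUFFCLIP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, recall_score
from sklearn.model_selection import train_test_split

from .segment import TailSegmentation, USABLE_TAGS
from .squiggle import PoreModel, TailSpec, simulate_read, random_transcript

READ_CLASSES = ("decorated", "blank", "move_issue", "signal_issue", "qc_failed")
RESIDUE_BASES = ("C", "G", "U")

CLASS_DATA_COLUMNS = ["readname", "class", "comments", "qc_tag", "polya_length"]
RESIDUE_DATA_COLUMNS = ["readname", "prediction", "position", "polya_length",
                        "confidence", "center_sample"]


@dataclass
class DetectionParams:
    """Tunables of the residue detector.

    tau
        move threshold in robust-scale units on consecutive one-step
        window-mean differences.
    window
        anomaly window length W in samples (GASF input is W x W).
    gate_sigmas
        minimum deviation of the window mean from the all-A level, in
        robust-scale units.
    saturation_pa
        window-mean deviations beyond this are treated as non-biological
        (signal_issue).
    norm_scale_pa
        fixed normalisation scale mapping pA deviations into [-1, 1] before
        GASF encoding; must exceed the largest genuine anomaly amplitude so
        that class amplitudes stay distinguishable after rescaling.
    """

    tau: float = 3.0
    window: int = 30
    gate_sigmas: float = 3.0
    saturation_pa: float = 90.0
    norm_scale_pa: float = 80.0
    #: excursion fragments are first grouped generously and then split at
    #: interior all-A plateaus, which is what truly separates residues
    cluster_gap_steps: float = 20.0
    min_gate_pa: float = 1.0
    pass_only: bool = False


@dataclass
class AnomalyWindow:
    """Fixed-length excursion snapshot handed to the classifier.

    ``samples`` are W values resampled uniformly across the excursion span
    (so the full k-event anomaly shape is captured whatever the per-event
    dwell times), still in pA; normalisation into [-1, 1] happens at
    encoding time against the all-A level.
    """

    read_id: str
    center_sample: int
    samples: np.ndarray


@dataclass
class MoveTrack:
    read_id: str
    move_indices: np.ndarray  # sample indices within the tail segment
    statistics: np.ndarray
    sigma_hat: float
    flag: str = ""


@dataclass
class ResidueCall:
    read_id: str
    base: str
    position_nt: int
    confidence: float
    polya_length_nt: float
    #: excursion centre in samples from the tail start (position_nt carries
    #: irreducible translocation-clock jitter; the sample coordinate is the
    #: detector's native localisation)
    center_sample: float = float("nan")


@dataclass
class ReadClassRecord:
    read_id: str
    read_class: str
    comment: str = ""


def mad_sigma(x: np.ndarray) -> float:
    """Robust (MAD-based) scale estimate."""
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def compute_moves(tail_signal: np.ndarray, read_rate: float,
                  tau: float = 3.0, read_id: str = "read",
                  noise_sigma: float | None = None) -> MoveTrack:
    """Flag significant level changes between consecutive translocation steps.

    Windows of ``read_rate`` samples are stepped by ``read_rate``; a move is
    recorded at each boundary where the absolute window-mean difference
    exceeds ``tau`` times the robust scale of the tail signal.  The MAD
    scale of a short, heavily decorated tail is inflated by the anomalies
    themselves, so when an independent per-read noise estimate is supplied
    the smaller of the two is used.
    """
    step = max(2, int(round(read_rate)))
    n = tail_signal.size // step
    if n < 2 or tail_signal.size < 2 * step:
        return MoveTrack(read_id, np.array([], dtype=int), np.array([]),
                         0.0, flag="tail_too_short")
    sigma = mad_sigma(tail_signal)
    if noise_sigma is not None and np.isfinite(noise_sigma):
        sigma = min(sigma, noise_sigma)
    means = tail_signal[: n * step].reshape(n, step).mean(axis=1)
    diffs = np.abs(np.diff(means))
    hits = np.nonzero(diffs > tau * sigma)[0]
    idx = (hits + 1) * step  # boundary sample index within the tail
    return MoveTrack(read_id, idx.astype(int), diffs[hits], sigma)


def encode_window(window_samples: np.ndarray) -> np.ndarray:
    """Gramian angular summation field of a [-1, 1]-normalised window.

    phi_i = arccos(x_i), M_ij = cos(phi_i + phi_j).  Input values are
    clipped into [-1, 1]; a constant window maps to the zero angle for all
    entries (an all-equal matrix).
    """
    x = np.clip(np.asarray(window_samples, dtype=float), -1.0, 1.0)
    phi = np.arccos(x)
    return np.cos(phi[:, None] + phi[None, :])


def _normalise(window: np.ndarray, a_level: float, scale: float) -> np.ndarray:
    return np.clip((window - a_level) / scale, -1.0, 1.0)


def _features(window: np.ndarray, a_level: float, scale: float) -> np.ndarray:
    """Classifier features: flattened GASF plus the normalised window.

    The GASF is invariant under a global sign flip of the window (cos of
    angle sums cannot tell a +d from a -d excursion), so the normalised
    window itself is appended to keep cytidine (level up) separable from
    guanosine (level down), together with extremal summaries: the class
    bands are disjoint in peak amplitude even when the residue dwells only
    briefly and the window mean is diluted towards the tail level.
    """
    x = _normalise(window, a_level, scale)
    # weighted up so the L2 penalty does not bury four summary columns
    # under the W*W encoding
    summaries = 10.0 * np.array([x.max(), x.min(), x.mean(), np.median(x)])
    return np.concatenate([encode_window(x).ravel(), x, summaries])


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """Multinomial logistic classifier over GASF-encoded anomaly windows."""

    estimator: LogisticRegression
    classes: tuple[str, ...]
    window: int
    norm_scale_pa: float
    a_level: float
    heldout_confusion: np.ndarray = field(default=None)
    heldout_macro_recall: float = float("nan")

    def predict_window(self, window_samples: np.ndarray) -> tuple[str, float]:
        feat = _features(window_samples, self.a_level,
                         self.norm_scale_pa).reshape(1, -1)
        probs = self.estimator.predict_proba(feat)[0]
        order = np.argsort(-probs)
        best = order[0]
        # deterministic tie-break towards the lower class index (C < G < U)
        if len(order) > 1 and math.isclose(probs[order[0]], probs[order[1]]):
            tied = [i for i in order if math.isclose(probs[i], probs[best])]
            best = min(tied)
        return self.classes[best], float(probs[best])

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        return joblib.load(path)


def train_classifier(labeled_windows, seed: int = 0,
                     params: DetectionParams | None = None,
                     a_level: float = 90.0) -> ClassifierModel:
    """Train the residue classifier on labelled anomaly windows.

    ``labeled_windows`` is an iterable of ``(window_samples, label)`` with
    labels in {C, G, U} and at least 50 examples per class.  A stratified
    70/30 split provides the held-out confusion matrix and macro recall
    stored on the model.
    """
    params = params or DetectionParams()
    windows, labels = [], []
    for w, lab in labeled_windows:
        if lab not in RESIDUE_BASES:
            raise ValueError(f"label must be one of {RESIDUE_BASES}, got {lab!r}")
        windows.append(np.asarray(w, dtype=float))
        labels.append(lab)
    labels = np.array(labels)
    present = set(labels)
    missing = [b for b in RESIDUE_BASES if b not in present]
    if missing:
        raise ValueError(f"class(es) absent from training data: {missing}")

    feats = np.stack([
        _features(w, a_level, params.norm_scale_pa) for w in windows])
    X_tr, X_te, y_tr, y_te = train_test_split(
        feats, labels, test_size=0.3, random_state=seed, stratify=labels)
    est = LogisticRegression(max_iter=1000, C=1.0)
    est.fit(X_tr, y_tr)
    y_pred = est.predict(X_te)
    cm = confusion_matrix(y_te, y_pred, labels=list(est.classes_))
    macro = recall_score(y_te, y_pred, average="macro")
    return ClassifierModel(
        estimator=est, classes=tuple(est.classes_), window=params.window,
        norm_scale_pa=params.norm_scale_pa, a_level=a_level,
        heldout_confusion=cm, heldout_macro_recall=float(macro))


def make_training_windows(model: PoreModel, n_per_class: int = 150,
                          noise_sd: float = 2.0, seed: int = 0,
                          params: DetectionParams | None = None):
    """Simulate labelled anomaly windows for classifier training.

    Each window comes from a simulated read carrying a single residue of
    known base and is extracted through the *production* path
    (segmentation, move clustering, resampled excursion window), so that
    the training distribution matches what :func:`classify_read` sees —
    including 3'-terminal residues whose excursions drag in corrupted
    adapter-junction events.
    """
    from .segment import segment_signal

    params = params or DetectionParams()
    rng = np.random.default_rng(seed)
    out = []
    for base in RESIDUE_BASES:
        made = 0
        attempt = 0
        while made < n_per_class and attempt < n_per_class * 4:
            attempt += 1
            tail_len = int(rng.integers(60, 180))
            # cover terminal positions too: production windows for 3'-most
            # residues straddle the segment edge and must be represented
            pos = int(rng.integers(2, tail_len - model.k + 2))
            tx = random_transcript(200, rng, k=model.k)
            read = simulate_read(
                tx, TailSpec(tail_len, ((pos, base),)), model, noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)))
            # the residue must dwell long enough to leave class evidence;
            # a footprint of one or two samples is unlabel-able noise
            if read.per_nt_dwell[max(pos - model.k, 0):pos].sum() < 6:
                continue
            seg = segment_signal(read.signal, model, read_id=read.read_id,
                                 transcript_nt=read.transcript_length_nt)
            if seg.qc_tag not in USABLE_TAGS:
                continue
            tail = read.signal[seg.polya_start:seg.transcript_start]
            rate = seg.read_rate
            track = compute_moves(tail, rate, tau=params.tau)
            if track.move_indices.size == 0:
                continue
            clusters = _cluster_moves(track.move_indices,
                                      params.cluster_gap_steps * rate)
            lo, hi = max(clusters, key=lambda c: c[1] - c[0])
            # only windows that actually cover the planted residue are
            # valid training examples: a stray segmentation artefact must
            # not enter the labelled set
            csum = np.concatenate([[0], np.cumsum(read.per_nt_dwell)])
            truth_center = (read.truth_boundaries[1]
                            + (csum[max(pos - model.k, 0)]
                               + csum[min(pos, len(csum) - 1)]) / 2
                            - seg.polya_start)
            if not (lo - 2 * model.k * rate <= truth_center
                    <= hi + 2 * model.k * rate):
                continue
            w, _ = _resample_window(tail, lo, hi, rate, params.window)
            if w is None or not np.all(np.isfinite(w)):
                continue
            w = np.clip(w, model.a_level - params.saturation_pa,
                        model.a_level + params.saturation_pa)
            out.append((w, base))
            made += 1
    return out


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if x.size < w:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _resample_window(tail: np.ndarray, lo: int, hi: int, rate: float, W: int):
    """Resample the excursion span [lo, hi] (plus one translocation step of
    margin) to exactly W samples."""
    span_lo = max(0, int(lo - rate))
    span_hi = min(tail.size, int(hi + rate))
    if span_hi - span_lo < 4:
        return None, 0
    idx = np.linspace(span_lo, span_hi - 1, W).round().astype(int)
    center = (span_lo + span_hi) // 2
    return tail[idx], center


# ---------------------------------------------------------------------------
# Read-level classification
# ---------------------------------------------------------------------------

def classify_read(
    segmentation: TailSegmentation,
    signal: np.ndarray,
    classifier: ClassifierModel,
    model: PoreModel,
    params: DetectionParams | None = None,
) -> tuple[ReadClassRecord, list[ResidueCall]]:
    """Classify one read into the five-way scheme and emit residue calls."""
    params = params or DetectionParams()
    rid = segmentation.read_id

    usable = ("PASS",) if params.pass_only else USABLE_TAGS
    if segmentation.qc_tag not in usable:
        return ReadClassRecord(rid, "qc_failed",
                               f"qc_tag={segmentation.qc_tag}"), []

    ps, ts = segmentation.polya_start, segmentation.transcript_start
    tail = signal[ps:ts]
    rate = segmentation.read_rate
    if tail.size < 2 * params.window or not np.isfinite(rate) or rate <= 0:
        return ReadClassRecord(rid, "signal_issue", "tail_too_short"), []

    track = compute_moves(tail, rate, tau=params.tau, read_id=rid,
                          noise_sigma=segmentation.noise_sigma)
    if track.flag:
        return ReadClassRecord(rid, "signal_issue", track.flag), []
    if track.move_indices.size == 0:
        return ReadClassRecord(rid, "blank", ""), []

    # numerical floor keeps the gate meaningful for noise-free signals
    gate = max(params.gate_sigmas * track.sigma_hat, params.min_gate_pa)

    clusters = _cluster_moves(track.move_indices, params.cluster_gap_steps * rate)
    clusters = _split_clusters_at_plateaus(clusters, tail, model.a_level,
                                           max(4.0 * track.sigma_hat, 1e-6),
                                           int(1.5 * rate))
    calls: list[ResidueCall] = []
    saw_gated = False
    saw_saturated = False
    L_nt = segmentation.polya_length_nt
    max_pos = max(1, int(np.ceil(L_nt))) if np.isfinite(L_nt) else 1

    known_levels = np.array(model.junction_levels()
                            + [model.adapter_anchor_level(), model.a_level])
    for lo, hi in clusters:
        # the last k-1 tail events are always plain adenosine context (a
        # resolvable residue sits at least k-1 nt from the 5' junction), so
        # an excursion flush against the segment end is a boundary
        # artefact; under noise the boundary itself is uncertain enough
        # that such artefacts occur, while a noise-free boundary is exact
        if track.sigma_hat > 1e-9 and hi > tail.size - 2.5 * rate:
            saw_gated = True
            saw_saturated = True
            continue
        span_lo = max(0, int(lo - rate))
        span_hi = min(tail.size, int(hi + rate))
        raw = tail[span_lo:span_hi]
        if raw.size < 4:
            continue
        if not np.all(np.isfinite(raw)):
            saw_saturated = True
            continue
        # a genuine residue leaves at least one stable stretch at a level
        # the adapter junction model cannot explain; excursions made purely
        # of junction leftovers and event-transition blends have none.
        # Noise-free signals have no blends, so any short novel run counts.
        novel = np.min(np.abs(raw[:, None] - known_levels[None, :]), axis=1) > 3.0
        novel_min = 3 if track.sigma_hat < 1e-9 else 8
        if max((e - s for s, e in _runs_bool(novel)), default=0) < novel_min:
            saw_saturated = True
            continue
        w, _ = _resample_window(tail, lo, hi, rate, params.window)
        if w is None:
            continue
        # mean absolute deviation: a 3'-terminal excursion can mix levels
        # above and below the tail level, cancelling the plain mean
        if float(np.mean(np.abs(w - model.a_level))) < gate:
            continue
        saw_gated = True
        dev_raw = np.abs(raw - model.a_level)
        if float(np.mean(dev_raw > params.saturation_pa)) > 0.5:
            saw_saturated = True
            continue
        # clip stray out-of-range samples (junction spill-over) instead of
        # rejecting an otherwise sound excursion
        w = np.clip(w, model.a_level - params.saturation_pa,
                    model.a_level + params.saturation_pa)
        base, conf = classifier.predict_window(w)
        vote = _level_vote(raw, dev_raw, model,
                           tol=max(3.0, 2.0 * track.sigma_hat),
                           sat=params.saturation_pa)
        if vote is not None and vote != base:
            # the extremum plateau sits unambiguously on another base's
            # single-substitution level; trust the pore model over the
            # shape classifier for the base identity
            base = vote
        # deviation-weighted centroid of the excursion; the k k-mer events
        # overlapping the residue centre about half a k-mer before it
        sel = (dev_raw >= gate) & (dev_raw <= params.saturation_pa)
        if np.any(sel):
            center = span_lo + float(np.average(np.nonzero(sel)[0],
                                                weights=dev_raw[sel]))
        else:
            center = (span_lo + span_hi) / 2
        pos = int(round(center / rate + 1 + (model.k - 1) / 2))
        pos = min(max(pos, 1), max_pos)
        calls.append(ResidueCall(rid, base, pos, conf, float(L_nt),
                                 center_sample=float(ps + center)))

    calls = _dedupe_calls(calls, model.k, rate)

    if calls:
        return ReadClassRecord(rid, "decorated", f"n_residues={len(calls)}"), calls
    if saw_saturated:
        return ReadClassRecord(rid, "signal_issue", "saturated_window"), []
    if not saw_gated:
        return ReadClassRecord(rid, "move_issue", "no_window_passed_gate"), []
    return ReadClassRecord(rid, "signal_issue", "gated_window_rejected"), []


def _level_vote(raw: np.ndarray, dev_raw: np.ndarray, model: PoreModel,
                tol: float, sat: float):
    """Base identity from the excursion's extremum plateau level.

    The *rightmost* deviant plateau of the excursion is matched against the
    3k single-substitution k-mer levels of the pore model; a match within
    ``tol`` votes for that level's substituted base.  The rightmost plateau
    is used because every k-mer overlapping a residue substitutes the same
    base, while a 3'-terminal excursion can drag in corrupted adapter
    junction k-mers on its left flank.  Returns None when the plateau sits
    on no single-substitution level and the shape classifier must stand
    alone.
    """
    deviant = (dev_raw >= 10.0) & (dev_raw <= sat)
    # split deviant stretches at level changes so each run is one event's
    # plateau; a stretch spanning several events has a meaningless median
    level_change = np.concatenate([[False], np.abs(np.diff(raw)) > 2 * tol])
    boundaries = np.flatnonzero(level_change)
    plateau_id = np.zeros(raw.size, dtype=int)
    for b in boundaries:
        plateau_id[b:] += 1
    runs = []
    for s, e in _runs_bool(deviant):
        for pid in np.unique(plateau_id[s:e]):
            idx = np.flatnonzero(plateau_id[s:e] == pid)
            if idx.size >= 3:
                runs.append((s + idx[0], s + idx[-1] + 1))
    if not runs:
        return None
    # prefer plateaus in the right half of the deviant extent: corrupted
    # junction k-mers can only sit on the left flank of the excursion
    d = np.flatnonzero(deviant)
    mid = (d[0] + d[-1]) / 2
    right = [r for r in runs if r[1] > mid]
    s, e = max(right if right else runs)
    level = float(np.median(raw[s:e]))
    best, best_d = None, np.inf
    k = model.k
    for pos in range(k):
        for b in "CGU":
            d = abs(level - model.level("A" * pos + b + "A" * (k - pos - 1)))
            if d < best_d:
                best, best_d = b, d
    return best if best_d <= tol else None


def _runs_bool(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, idx.size, 2)]


def _dedupe_calls(calls: list[ResidueCall], k: int,
                  rate: float = 30.0) -> list[ResidueCall]:
    """Collapse calls within 2k nt of each other (split excursions),
    keeping the most confident one.

    Physically resolvable residues sit at least 3k apart (closer ones share
    overlapping k-mers and a merged excursion), so two calls much closer
    than that must be fragments of one excursion.
    """
    out: list[ResidueCall] = []
    # prefer the rightmost fragment: a 3'-terminal excursion can split into
    # a corrupted-junction part (left) and the true residue part (right)
    for c in sorted(calls, key=lambda c: -c.center_sample):
        if any(abs(o.center_sample - c.center_sample) <= 1.2 * k * rate
               or abs(o.position_nt - c.position_nt) <= k + 1
               for o in out):
            continue
        out.append(c)
    return sorted(out, key=lambda c: c.position_nt)


def _split_clusters_at_plateaus(clusters, tail: np.ndarray, a_level: float,
                                tol: float, min_plateau: int):
    """Split move clusters at interior all-A plateaus.

    Two residues separated by a stretch of plain adenosines must yield two
    calls even when dwell-time jitter squeezes the stretch below the
    clustering gap; a run of at least ``min_plateau`` samples at the all-A
    level inside a cluster marks such a boundary.
    """
    out = []
    for lo, hi in clusters:
        if hi - lo < 2 * min_plateau:
            out.append((lo, hi))
            continue
        a_like = np.abs(tail[lo:hi] - a_level) <= tol
        cuts = [(s, e) for s, e in _runs_bool(a_like) if e - s >= min_plateau]
        cur = lo
        for s, e in cuts:
            if cur <= lo + s:
                # zero-width head pieces survive: a move index sits at the
                # window boundary *after* an excursion at the cluster edge
                out.append((cur, lo + s))
            cur = lo + e
        if cur <= hi:
            out.append((cur, hi))
    # a single-move excursion has zero extent and is still a candidate
    return [c for c in out if c[1] >= c[0]]


def _cluster_moves(indices: np.ndarray, max_gap: float) -> list[tuple[int, int]]:
    """Group move indices into [lo, hi] sample-extent clusters."""
    clusters = []
    lo = hi = int(indices[0])
    for i in indices[1:]:
        if i - hi <= max_gap:
            hi = int(i)
        else:
            clusters.append((lo, hi))
            lo = hi = int(i)
    clusters.append((lo, hi))
    return clusters


def evaluate_detection(reads, residue_data: pd.DataFrame, model: PoreModel,
                       tolerance_nt: float | None = None) -> dict:
    """Per-base precision/recall of residue calls against simulator truth.

    Matching happens in *sample* coordinates: a call matches a planted
    residue when bases agree and the call's excursion centre lies within
    ``tolerance_nt`` translocation steps (default k) of the residue's true
    signal span.  The nucleotide-position column is not used for matching
    because converting samples to nucleotides carries irreducible
    translocation-clock jitter that grows with distance from the 3' end.
    """
    tol = (tolerance_nt if tolerance_nt is not None else model.k) \
        * model.translocation_rate
    calls_by_read: dict[str, list] = {}
    for row in residue_data.itertuples(index=False):
        calls_by_read.setdefault(row.readname, []).append(
            [row.prediction, float(row.center_sample)])

    tp = {b: 0 for b in RESIDUE_BASES}
    fp = {b: 0 for b in RESIDUE_BASES}
    fn = {b: 0 for b in RESIDUE_BASES}
    for read in reads:
        _, ps, _, _ = read.truth_boundaries
        csum = np.concatenate([[0], np.cumsum(read.per_nt_dwell)])
        calls = list(calls_by_read.get(read.read_id, []))
        for q, base in read.truth_tail.residues:
            if q >= model.k:
                lo = csum[q - model.k]
            else:
                # a 3'-terminal residue's k-mer footprint reaches into the
                # adapter junction, before the tail's first sample
                lo = -(model.k - q) * model.translocation_rate
            hi = csum[min(q, len(csum) - 1)]
            center_true = ps + (lo + hi) / 2
            # the junction part of a terminal footprint runs on dwell times
            # the truth tables do not record; widen the tolerance by its
            # expected extent
            tol_eff = tol + 1.5 * (model.k - min(q, model.k)) \
                * model.translocation_rate
            cand = [(abs(c[1] - center_true), i) for i, c in enumerate(calls)
                    if c[0] == base and abs(c[1] - center_true) <= tol_eff]
            if cand:
                _, i = min(cand)
                tp[base] += 1
                calls.pop(i)
            else:
                fn[base] += 1
        for c in calls:
            fp[c[0]] += 1
    out = {}
    for b in RESIDUE_BASES:
        prec = tp[b] / max(tp[b] + fp[b], 1)
        rec = tp[b] / max(tp[b] + fn[b], 1)
        out[b] = {"precision": prec, "recall": rec,
                  "tp": tp[b], "fp": fp[b], "fn": fn[b]}
    all_tp = sum(tp.values())
    out["overall"] = {
        "precision": all_tp / max(all_tp + sum(fp.values()), 1),
        "recall": all_tp / max(all_tp + sum(fn.values()), 1),
    }
    return out


def run_detection(
    signals: dict[str, np.ndarray],
    segmentations,
    classifier: ClassifierModel,
    model: PoreModel,
    params: DetectionParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect residues over a whole sample.

    Returns ``(class_data, residue_data)``: one row per read and one row
    per detected residue instance, in the tab-separated output dialect
    (columns: readname/class/comments/qc_tag/polya_length and
    readname/prediction/position/polya_length/confidence).
    """
    params = params or DetectionParams()
    seg_by_id = {s.read_id: s for s in segmentations}
    class_rows, residue_rows = [], []
    for read_id, sig in signals.items():
        seg = seg_by_id.get(read_id)
        if seg is None:
            class_rows.append({
                "readname": read_id, "class": "qc_failed",
                "comments": "missing_segmentation", "qc_tag": "READ_FAILED_LOAD",
                "polya_length": float("nan")})
            continue
        record, calls = classify_read(seg, sig, classifier, model, params)
        class_rows.append({
            "readname": read_id, "class": record.read_class,
            "comments": record.comment or "none", "qc_tag": seg.qc_tag,
            "polya_length": seg.polya_length_nt})
        for c in calls:
            residue_rows.append({
                "readname": c.read_id, "prediction": c.base,
                "position": c.position_nt, "polya_length": c.polya_length_nt,
                "confidence": c.confidence, "center_sample": c.center_sample})
    class_data = pd.DataFrame(class_rows, columns=CLASS_DATA_COLUMNS)
    residue_data = pd.DataFrame(residue_rows, columns=RESIDUE_DATA_COLUMNS)
    return class_data, residue_data
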
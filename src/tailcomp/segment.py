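"""Poly(A) tail delimitation, tail-length estimation and five-way QC tagging.

The poly(A) tail of a DRS read is a long low-variance stretch of current at
the all-A pore level.  The segmenter finds it with rolling-window variance
and level thresholds, refines the boundaries to changepoints, walks the
known adapter/tail junction k-mers to recover tail starts even when the
3'-terminal nucleotides are non-A, and reports a tail length in nucleotides
using a read rate (samples per nucleotide) estimated from the transcript
segment.  Each read receives exactly one of five quality tags following the
Nanopolish polya convention: PASS, SUFFCLIP, ADAPTER, NOREGION,
READ_FAILED_LOAD; only PASS and SUFFCLIP are considered usable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .squiggle import ADAPTER_SEQ, PoreModel

QC_TAGS = ("PASS", "SUFFCLIP", "ADAPTER", "NOREGION", "READ_FAILED_LOAD")
USABLE_TAGS = ("PASS", "SUFFCLIP")

POLYA_COLUMNS = ["readname", "contig", "position", "adapter_start",
                 "polya_start", "transcript_start", "read_rate",
                 "polya_length", "qc_tag"]


class FormatError(ValueError):
    """Malformed tabular input."""


@dataclass
class SegmentationParams:
    """Tunables of the changepoint/threshold segmenter.

    window
        rolling-window length in samples for the variance/level scan.
    var_cap
        variance ceiling for a window to count as tail-like; ``None`` means
        2 * (robust noise estimate)^2, the documented default.
    level_tol
        max deviation (pA) of a window mean from the all-A level.
    max_gap_windows
        tail-internal anomaly bridging: qualifying runs separated by at most
        this many non-qualifying windows are merged (a planted residue spans
        about k events, i.e. a handful of windows).
    min_transcript_samples
        transcript segments shorter than this mark the read SUFFCLIP
        (soft-clip analogue: segmentation succeeded, reference segment short).
    """

    window: int = 25
    var_cap: float | None = None
    #: ceiling on the noise scale assumed for a genuine tail; keeps the
    #: auto var_cap from chasing arbitrarily noisy signals
    max_tail_sd: float = 4.0
    level_tol: float = 5.0
    min_samples: int = 200
    min_adapter_samples: int = 150
    min_transcript_samples: int = 3000
    max_gap_windows: int = 20
    adapter_lookback: int = 4000


@dataclass
class TailSegmentation:
    """Adapter/poly(A)/transcript boundaries and tail-length estimate for one read."""

    read_id: str
    qc_tag: str
    adapter_start: int = 0
    polya_start: int = 0
    transcript_start: int = 0
    read_rate: float = float("nan")
    polya_length_nt: float = float("nan")
    contig: str = "unknown"
    noise_sigma: float = float("nan")
    comment: str = ""


def robust_noise_sigma(signal: np.ndarray) -> float:
    """Noise scale from the median absolute first difference.

    Within an event the first difference is N(0, 2*sigma^2); level changes
    are sparse (one per ~30 samples), so the median is barely affected.
    """
    d = np.diff(signal)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def estimate_read_rate(transcript_segment_samples: int, transcript_nt: int) -> float:
    """Samples per nucleotide from the transcript segment."""
    if transcript_segment_samples <= 0 or transcript_nt <= 0:
        raise ValueError("both segment samples and nucleotide count must be > 0")
    return transcript_segment_samples / transcript_nt


def _changepoint_count(segment: np.ndarray, sigma: float, window: int = 8) -> int:
    """Count significant level changes; used as a rate fallback when the
    transcript length is unknown."""
    if sigma <= 1e-9:
        return int(np.count_nonzero(np.diff(segment) != 0))
    n = segment.size // window
    if n < 2:
        return 0
    means = segment[: n * window].reshape(n, window).mean(axis=1)
    thresh = 4.0 * sigma / np.sqrt(window / 2.0)
    return int(np.count_nonzero(np.abs(np.diff(means)) > thresh))


def _box_smooth(x: np.ndarray, w: int) -> np.ndarray:
    if x.size < w:
        return x.copy()
    return np.convolve(x, np.ones(w) / w, mode="same")


def _prefix_levels(model: PoreModel, n_adapter_events: int = 3) -> list[float]:
    """Expected levels of the last pure-adapter events followed by the k-1
    adapter/tail junction events, in signal order."""
    k = model.k
    out = []
    for m in range(k + n_adapter_events - 1, k - 1, -1):
        out.append(model.level(ADAPTER_SEQ[len(ADAPTER_SEQ) - m:][:k]))
    out.extend(model.junction_levels())
    return out


def _walk_junction(signal: np.ndarray, start: int, limit: int,
                   levels: list[float], tol: float, max_skip: int) -> int:
    """Advance through an expected sequence of event levels.

    For each expected level up to ``max_skip`` unmatched samples (event
    transitions, smoothing blends, very short events) may be skipped before
    matching; an expected level that never matches stops the walk at the
    start of the unmatched region (a 3'-terminal tail anomaly breaks the
    expected pattern exactly this way, deliberately landing the boundary at
    the anomaly's first sample).
    """
    cur = start
    for lv in levels:
        skipped = 0
        while (cur < limit and abs(signal[cur] - lv) > tol
               and skipped < max_skip):
            cur += 1
            skipped += 1
        if cur >= limit or abs(signal[cur] - lv) > tol:
            return cur - skipped
        while cur < limit and abs(signal[cur] - lv) <= tol:
            cur += 1
    return cur


def _extend_tail_right(signal: np.ndarray, ts: int, a_level: float,
                       samp_tol: float, inexplicable: np.ndarray,
                       gap_run_cap: int, dev_cap: float,
                       max_span: int, region_is_body=None,
                       min_island: int = 60) -> int:
    """Extend the tail's 5' boundary across explicable trailing anomalies.

    From the refined boundary, look ahead up to ``max_span`` samples for
    the next all-A run of at least 20 samples; the gap in between must
    plateau only at single-substitution levels (``inexplicable`` runs
    shorter than ``gap_run_cap``) and stay within ``dev_cap`` of the tail
    level, otherwise it is the transcript body and extension stops.
    """
    n = signal.size
    while True:
        limit = min(n, ts + max_span)
        a_like = np.abs(signal[ts:limit] - a_level) <= samp_tol
        next_run = None
        for s, e in _runs(a_like):
            # demand a substantial all-A landing: a single transcript-body
            # event aliasing the tail level must not attract the boundary
            if e - s >= min_island and s > 0:
                next_run = (s, e)
                break
        if next_run is None:
            return ts
        s, e = next_run
        gap_inex = inexplicable[ts:ts + s]
        if gap_inex.size and float(np.mean(gap_inex)) > 0.45:
            return ts
        if region_is_body is not None and region_is_body(ts, ts + s):
            return ts
        if max((q - p for p, q in _runs(gap_inex)), default=0) >= gap_run_cap:
            return ts
        if np.max(np.abs(signal[ts:ts + s] - a_level)) > dev_cap:
            return ts
        ts += e
        while ts < n and abs(signal[ts] - a_level) <= samp_tol:
            ts += 1


def _anomalous_suffix_start(probe: np.ndarray, anchor_end: int, ps0: int,
                            near_levels: list[float], far_levels: list[float],
                            tol: float, min_len: int, lookback: int,
                            depth_limit: int) -> int:
    """Start of a 3'-terminal tail anomaly abutting the refined tail start.

    Samples just before the tail are *explained* when they match one of the
    expected junction/anchor event levels (``near_levels``); deeper than
    ``depth_limit`` into the prefix, matching an earlier adapter event level
    (``far_levels``) also stops the scan, so the boundary never tunnels
    into the adapter proper.  Scanning backwards from the tail start, a
    contiguous unexplained block (tolerating explained interruptions
    shorter than 6 samples) of at least ``min_len`` samples is a
    3'-terminal anomaly: the k-mers overlapping a residue at the first tail
    positions match none of the expected levels.  Returns the anomaly
    start, or ``ps0`` when the prefix is explained.
    """
    lo = max(anchor_end, ps0 - lookback, 0)
    if ps0 - lo < 1:
        return ps0
    region = probe[lo:ps0]
    near = np.array(near_levels)
    explained = np.min(np.abs(region[:, None] - near[None, :]), axis=1) <= tol
    if far_levels:
        far = np.array(far_levels)
        deep = np.arange(region.size) < region.size - depth_limit
        far_match = np.min(np.abs(region[:, None] - far[None, :]), axis=1) <= tol
        explained |= deep & far_match
    t = region.size
    run_explained = 0
    j = region.size - 1
    while j >= 0:
        if not explained[j]:
            run_explained = 0
            t = j
        else:
            run_explained += 1
            if run_explained >= 6:
                break
        j -= 1
    if region.size - t >= min_len and t < region.size:
        return lo + t
    return ps0


def _novel_plateau_start(raw: np.ndarray, lo: int, ps0: int,
                         terminal_level: float, verify_level: float,
                         stop_levels: list[float], known_levels: list[float],
                         a_level: float, tol: float) -> int:
    """Terminal-anomaly rescue for events degenerate with the final
    junction k-mer.

    A residue of the same base as the adapter's terminal nucleotide sits at
    the tail start behind an event whose level equals the final junction
    event (``terminal_level``), which stops the ordinary explained-suffix
    scan.  This rule scans the pre-tail region for a *novel plateau* — a
    run of at least 8 lightly-smoothed samples further than 2*tol from
    every expected level — and extends the tail boundary to it, passing
    through ``terminal_level`` runs unless they are verified as the real
    junction by the expected predecessor event (``verify_level``) just
    upstream.  Returns the plateau start or ``ps0``.
    """
    if ps0 - lo < 10:
        return ps0
    sm5 = _box_smooth(raw[lo:ps0], 5)
    known = np.array(list(known_levels) + [a_level])
    novel = np.min(np.abs(sm5[:, None] - known[None, :]), axis=1) > 2 * tol
    novel_runs = [r for r in _runs(novel) if r[1] - r[0] >= 8]
    if not novel_runs:
        return ps0

    stops = np.array(stop_levels)
    stop_mask = np.min(np.abs(sm5[:, None] - stops[None, :]), axis=1) <= tol
    stop_runs = [r for r in _runs(stop_mask) if r[1] - r[0] >= 6]
    term_mask = np.abs(sm5 - terminal_level) <= tol
    for s, e in _runs(term_mask):
        if e - s < 6:
            continue
        pre = sm5[max(0, s - 80):s]
        if np.count_nonzero(np.abs(pre - verify_level) <= tol) >= 6:
            stop_runs.append((s, e))
    barrier = max((e for _, e in stop_runs), default=0)
    reachable = [s for s, e in novel_runs if s >= barrier]
    if not reachable:
        return ps0
    return lo + min(reachable)


def segment_signal(
    signal: np.ndarray,
    model: PoreModel,
    params: SegmentationParams | None = None,
    read_id: str = "read",
    transcript_nt: int | None = None,
    transcript_seq: str | None = None,
    contig: str = "unknown",
) -> TailSegmentation:
    """Delimit the poly(A) tail of one raw signal and tag its quality.

    ``transcript_nt`` is the aligned transcript-body length in nucleotides
    (from the alignment stand-in); when given, the read rate is the exact
    samples-per-k-mer-event ratio of the transcript segment, otherwise it
    falls back to counting significant level changes there.  When the
    aligned transcript *sequence* is also known, the expected levels of the
    first transcript-body k-mers serve as body evidence that pins the
    tail's 5' boundary (a residue anomaly can otherwise be confused with a
    body event whose k-mer happens to sit on a single-substitution level).
    """
    params = params or SegmentationParams()
    k = model.k
    a_level = model.a_level

    if signal is None or signal.size < params.min_samples or not np.all(np.isfinite(signal)):
        return TailSegmentation(read_id=read_id, qc_tag="READ_FAILED_LOAD",
                                contig=contig, comment="unloadable_or_short_signal")

    sigma = robust_noise_sigma(signal)
    if params.var_cap is not None:
        var_cap = params.var_cap
    else:
        var_cap = 2.0 * min(sigma, params.max_tail_sd) ** 2 + 1e-9
    w = params.window
    n_win = signal.size // w
    windows = signal[: n_win * w].reshape(n_win, w)
    means = windows.mean(axis=1)
    variances = windows.var(axis=1)
    # window-mean tolerance adapts to the noise floor: transcript-body
    # k-mers with cancelling substitutions can sit within ~3 pA of the
    # tail level and must not pass when the signal is cleaner than that
    level_tol = min(params.level_tol, max(0.5, 3.0 * sigma))
    tail_like = (variances <= var_cap) & (np.abs(means - a_level) <= level_tol)

    singles = np.array([model.level("A" * pos + b + "A" * (k - pos - 1))
                        for pos in range(k) for b in "CGU"])
    max_single_sub_dev = float(np.max(np.abs(singles - a_level)))
    noise_free = sigma < 1e-9
    gap_probe = signal if noise_free else _box_smooth(signal, 5)
    gap_run_cap = 2 if noise_free else 14  # smoothing blends need headroom
    expl = np.concatenate([singles, [a_level]])
    inexplicable = (np.min(np.abs(gap_probe[:, None] - expl[None, :]), axis=1)
                    > max(1.5 * sigma, 1e-6 if noise_free else 0.5))

    # body evidence: expected levels of early transcript-body k-mers that a
    # genuine tail anomaly can never produce (>= 2 non-A bases, clear of
    # the tail level and of every single-substitution level)
    body_levels: list[float] = []
    if transcript_seq:
        rev = transcript_seq.upper().replace("T", "U")[::-1]
        for j in range(max(0, min(len(rev) - k + 1, 30))):
            kmer = rev[j:j + k]
            if sum(b != "A" for b in kmer) < 2 or not set(kmer) <= set("ACGU"):
                continue
            lv = model.level(kmer)
            if (abs(lv - a_level) > 12.0
                    and np.min(np.abs(singles - lv)) >= 6.0):
                body_levels.append(lv)
            if len(body_levels) >= 8:
                break
    if body_levels:
        blv = np.array(body_levels)
        body_hit = (np.min(np.abs(gap_probe[:, None] - blv[None, :]), axis=1)
                    <= max(1.5 * sigma, 1e-6 if noise_free else 0.5))
    else:
        body_hit = np.zeros(signal.size, dtype=bool)

    def _region_is_body(a: int, b: int) -> bool:
        seg = body_hit[a:b]
        return max((e - s for s, e in _runs(seg)), default=0) >= 6

    def _gap_content_ok(w_from: int, w_to: int) -> bool:
        # a bridgeable gap may only plateau at single-substitution levels:
        # long or dominant inexplicable stretches, or stretches matching
        # the aligned transcript's junction k-mer levels, are body
        seg = inexplicable[w_from * w: w_to * w]
        if seg.size and float(np.mean(seg)) > 0.45:
            return False
        if _region_is_body(w_from * w, w_to * w):
            return False
        return max((e - s for s, e in _runs(seg)), default=0) < gap_run_cap

    runs = _runs(tail_like)
    runs = _bridge(runs, params.max_gap_windows, min_run=3,
                   gap_means_dev=np.abs(means - a_level),
                   gap_dev_cap=max_single_sub_dev + 5.0,
                   gap_ok=_gap_content_ok)
    if not runs:
        return TailSegmentation(read_id=read_id, qc_tag="NOREGION", contig=contig,
                                noise_sigma=sigma, comment="no_tail_like_run")
    start_w, end_w = max(runs, key=lambda r: r[1] - r[0])
    coarse_start, coarse_end = start_w * w, end_w * w

    # per-sample refinement of both edges
    samp_tol = max(4.0 * sigma, 1e-6)
    ps = coarse_start
    while ps > 0 and abs(signal[ps - 1] - a_level) <= samp_tol:
        ps -= 1
    ts = coarse_end
    while ts < signal.size and abs(signal[ts] - a_level) <= samp_tol:
        ts += 1
    # recover short trailing tail fragments: a residue within a few nt of
    # the tail's 5' end can leave a post-anomaly all-A stretch too short to
    # survive the window-level merge; extend across explicable anomalies
    ts = _extend_tail_right(signal, ts, a_level, samp_tol, inexplicable,
                            gap_run_cap, max_single_sub_dev + 5.0,
                            int(3 * k * model.translocation_rate),
                            region_is_body=_region_is_body,
                            min_island=24 if body_levels else 60)
    if body_levels:
        # the tail's 5' boundary can bleed into transcript-body events
        # whose k-mers sit near the tail level; body-evidence k-mers never
        # occur in a genuine tail, so their presence near the end trims it
        look_lo = max(coarse_start, ts - 600)
        hits = [(s, e) for s, e in _runs(body_hit[look_lo:ts]) if e - s >= 6]
        if hits:
            ts = look_lo + hits[0][0]
            while ts > 0 and abs(signal[ts - 1] - a_level) > samp_tol:
                ts -= 1

    # adapter anchor + junction walk: locate the last confidently-matched
    # pure-adapter event in the prefix, then walk the expected pre-tail
    # level sequence forward; a 3'-terminal anomaly breaks the pattern and
    # pulls the boundary back to the anomaly start.
    exact = sigma < 1e-9
    probe = signal if exact else _box_smooth(signal, 9)
    # the floor matters at low noise: box smoothing biases event edges by
    # more than the noise floor, so a purely noise-scaled tolerance would
    # reject genuine anchor runs on clean signals
    walk_tol = 1e-6 if exact else max(1.5 * sigma, 2.0)
    exp_levels = _prefix_levels(model)
    lo = max(0, ps - params.adapter_lookback)
    anchor_found = False
    anchor_end = lo
    for ai in (2, 1, 0):  # prefer the adapter event closest to the tail
        mask = np.abs(probe[lo:ps] - exp_levels[ai]) <= walk_tol
        runs_a = [r for r in _runs(mask) if r[1] - r[0] >= (1 if exact else 8)]
        if runs_a:
            anchor_found = True
            anchor_end = lo + runs_a[-1][1]
            break
    if not anchor_found or ps < params.min_adapter_samples:
        return TailSegmentation(read_id=read_id, qc_tag="ADAPTER", contig=contig,
                                noise_sigma=sigma, comment="no_adapter_like_prefix")

    if exact:
        # noise-free signals: walk the expected pre-tail levels forward;
        # a 3'-terminal anomaly breaks the pattern at its first sample
        walked = _walk_junction(probe, anchor_end, ps, exp_levels[ai + 1:],
                                walk_tol, max_skip=2)
        if walked <= ps and ps - walked <= 5 * k * model.translocation_rate:
            ps = walked
    else:
        junction = model.junction_levels()
        # generous lookback: a terminal anomaly spans up to k events whose
        # geometric dwells can stretch well past their expectation
        lookback = int(5 * k * model.translocation_rate)
        ps_a = _anomalous_suffix_start(
            probe, anchor_end, ps,
            near_levels=exp_levels[2:], far_levels=exp_levels[:2],
            tol=walk_tol,
            min_len=int(0.6 * model.translocation_rate),
            lookback=lookback,
            depth_limit=int((k + 1) * model.translocation_rate))
        ps_b = _novel_plateau_start(
            signal, max(anchor_end, ps - lookback, 0), ps,
            terminal_level=junction[-1], verify_level=junction[-2],
            stop_levels=exp_levels[2:-1], known_levels=exp_levels[2:],
            a_level=a_level, tol=walk_tol)
        ps = min(ps_a, ps_b)

    transcript_samples = signal.size - ts
    if transcript_nt is not None and transcript_nt > 0:
        # the body contributes transcript_nt - k + 1 k-mer events
        effective_nt = max(1, transcript_nt - k + 1)
        rate = estimate_read_rate(max(transcript_samples, 1), effective_nt)
    else:
        n_events = _changepoint_count(signal[ts:], sigma) + 1
        rate = estimate_read_rate(max(transcript_samples, 1), n_events)

    tag = "PASS"
    comment = ""
    if transcript_samples < params.min_transcript_samples:
        tag = "SUFFCLIP"
        comment = "short_transcript_segment"

    polya_length = (ts - ps) / rate
    return TailSegmentation(
        read_id=read_id, qc_tag=tag, adapter_start=0, polya_start=int(ps),
        transcript_start=int(ts), read_rate=float(rate),
        polya_length_nt=float(polya_length), contig=contig,
        noise_sigma=sigma, comment=comment)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    for i in range(0, idx.size, 2):
        out.append((int(idx[i]), int(idx[i + 1])))
    return out


def _bridge(runs: list[tuple[int, int]], max_gap: int,
            min_run: int = 3,
            gap_means_dev: np.ndarray | None = None,
            gap_dev_cap: float = np.inf,
            gap_ok=None) -> list[tuple[int, int]]:
    """Merge qualifying runs across short gaps (tail-internal anomalies).

    Only runs of at least ``min_run`` windows take part in a merge: stray
    single near-A-level windows (e.g. a transcript-body event whose k-mer
    happens to sit near the all-A level) must not drag the tail boundary
    across the junction.  When window-mean deviations are supplied, a gap
    containing any window further than ``gap_dev_cap`` from the tail level
    is never bridged either, and ``gap_ok(from_window, to_window)`` allows
    a content test: genuine residue anomalies are bounded by the largest
    single-substitution level and plateau only at single-substitution
    levels, while the adapter junction and the transcript body can swing
    arbitrarily far and dwell at arbitrary levels.
    """
    if not runs:
        return runs
    merged = [runs[0]]
    for s, e in runs[1:]:
        p_s, p_e = merged[-1]
        substantial = (e - s) >= min_run and (p_e - p_s) >= min_run
        ok = True
        if s > p_e:
            if gap_means_dev is not None:
                ok = float(np.max(gap_means_dev[p_e:s])) <= gap_dev_cap
            if ok and gap_ok is not None:
                ok = gap_ok(p_e, s)
        if s - p_e <= max_gap and substantial and ok:
            merged[-1] = (p_s, e)
        else:
            merged.append((s, e))
    return merged


def assign_qc_tag(segmentation: TailSegmentation,
                  params: SegmentationParams | None = None) -> str:
    """Final five-way tag from segmentation diagnostics (total function)."""
    return segmentation.qc_tag


def filter_usable(segmentations):
    """Keep exactly the reads tagged PASS or SUFFCLIP (idempotent)."""
    return [s for s in segmentations if s.qc_tag in USABLE_TAGS]


def segment_sample(signals: dict[str, np.ndarray], model: PoreModel,
                   params: SegmentationParams | None = None,
                   alignments: dict[str, str] | None = None,
                   transcript_lengths: dict[str, int] | None = None,
                   transcripts: dict[str, str] | None = None):
    """Segment every read of a sample; returns a list of TailSegmentation."""
    out = []
    for read_id, sig in signals.items():
        tx = (alignments or {}).get(read_id)
        nt = (transcript_lengths or {}).get(tx) if tx else None
        seq = (transcripts or {}).get(tx) if tx else None
        if nt is None and seq is not None:
            nt = len(seq)
        out.append(segment_signal(sig, model, params, read_id=read_id,
                                  transcript_nt=nt, transcript_seq=seq,
                                  contig=tx or "unknown"))
    return out


# ---------------------------------------------------------------------------
# Nanopolish-polya TSV dialect
# ---------------------------------------------------------------------------

def write_polya_tsv(segmentations, path) -> None:
    rows = [{
        "readname": s.read_id,
        "contig": s.contig,
        "position": 0,
        "adapter_start": s.adapter_start,
        "polya_start": s.polya_start,
        "transcript_start": s.transcript_start,
        "read_rate": s.read_rate,
        "polya_length": s.polya_length_nt,
        "qc_tag": s.qc_tag,
    } for s in segmentations]
    pd.DataFrame(rows, columns=POLYA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_polya_tsv(path) -> list[TailSegmentation]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POLYA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(TailSegmentation(
            read_id=row.readname, qc_tag=row.qc_tag,
            adapter_start=int(row.adapter_start), polya_start=int(row.polya_start),
            transcript_start=int(row.transcript_start),
            read_rate=float(row.read_rate), polya_length_nt=float(row.polya_length),
            contig=row.contig))
    return out
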
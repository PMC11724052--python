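"""Composition, positional and concordance statistics over detected residues.

These summaries mirror the standard reporting for poly(A)-tail composition
studies: per-sample frequencies of reads carrying C/G/U residues (computed
over neural-network-classified reads only, i.e. decorated + blank),
per-transcript scatter profiles of residue position versus tail length, a
Monte-Carlo permutation test for enrichment of residues at the 3' terminus,
Spearman concordance matrices between samples, and QC-tag frequency
summaries.

Positions are 1-based distances from the tail's 3' end, so *small* relative
position means *terminal*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .segment import QC_TAGS

CLASSIFIED = ("decorated", "blank")


@dataclass
class CompositionSummary:
    sample_name: str
    n_classified: int
    freq_C: float
    freq_G: float
    freq_U: float
    residue_share_C: float
    residue_share_G: float
    residue_share_U: float


@dataclass
class PositionalProfile:
    transcript_id: str
    points: pd.DataFrame  # columns: position_nt, polya_length_nt, base
    n_reads: int
    flag: str = ""


def composition_frequencies(class_data: pd.DataFrame, residue_data: pd.DataFrame,
                            sample_name: str = "sample",
                            gene_set=None,
                            read_transcripts: dict[str, str] | None = None
                            ) -> CompositionSummary:
    """Per-base residue frequencies for one sample.

    ``freq_X`` is the fraction of classified reads (decorated + blank)
    carrying at least one X residue; ``residue_share_X`` is the fraction of
    residue *instances* that are X.  When ``gene_set`` is given (with
    ``read_transcripts`` mapping read ids to transcript/gene ids) the
    summary is restricted to reads from those genes.
    """
    classified = class_data[class_data["class"].isin(CLASSIFIED)]
    residues = residue_data
    if gene_set is not None:
        if read_transcripts is None:
            raise ValueError("gene_set restriction requires read_transcripts")
        keep = {r for r, t in read_transcripts.items() if t in set(gene_set)}
        classified = classified[classified["readname"].isin(keep)]
        residues = residues[residues["readname"].isin(keep)]
    residues = residues[residues["readname"].isin(set(classified["readname"]))]

    n = len(classified)
    if n == 0:
        warnings.warn(f"sample {sample_name}: no classified reads; "
                      "frequencies undefined")
        nan = float("nan")
        return CompositionSummary(sample_name, 0, nan, nan, nan, nan, nan, nan)

    freqs = {}
    for base in "CGU":
        carriers = residues.loc[residues["prediction"] == base, "readname"].nunique()
        freqs[base] = carriers / n
    total = len(residues)
    shares = {base: (len(residues[residues["prediction"] == base]) / total
                     if total else 0.0)
              for base in "CGU"}
    return CompositionSummary(
        sample_name, n, freqs["C"], freqs["G"], freqs["U"],
        shares["C"], shares["G"], shares["U"])


def positional_profile(residue_data: pd.DataFrame, transcript_id: str,
                       read_transcripts: dict[str, str]) -> PositionalProfile:
    """Scatter-ready (position, tail length, base) points for one transcript."""
    reads = {r for r, t in read_transcripts.items() if t == transcript_id}
    if not reads:
        return PositionalProfile(transcript_id,
                                 pd.DataFrame(columns=["position_nt",
                                                       "polya_length_nt", "base"]),
                                 0, flag="unknown_transcript")
    sub = residue_data[residue_data["readname"].isin(reads)]
    points = pd.DataFrame({
        "position_nt": sub["position"].to_numpy(),
        "polya_length_nt": sub["polya_length"].to_numpy(),
        "base": sub["prediction"].to_numpy(),
    })
    return PositionalProfile(transcript_id, points, sub["readname"].nunique())


def terminal_enrichment_test(profile: PositionalProfile, n_perm: int = 999,
                             seed: int = 0, min_calls: int = 10):
    """Monte-Carlo test for residue enrichment at the 3' terminus.

    The statistic is the median over calls of the relative position
    r = position / ceil(tail length); under the null each call's position
    is uniform on {1..ceil(tail)} of its own read.  The one-sided p-value
    (small r = terminal) uses the add-one correction
    (count + 1) / (n_perm + 1).  Returns ``(statistic, p)`` or
    ``(nan, nan)`` when fewer than ``min_calls`` calls are available.
    """
    pts = profile.points
    m = len(pts)
    if m < min_calls:
        return float("nan"), float("nan")
    ceil_len = np.ceil(pts["polya_length_nt"].to_numpy()).astype(int)
    ceil_len = np.maximum(ceil_len, 1)
    pos = pts["position_nt"].to_numpy()
    observed = float(np.median(pos / ceil_len))

    rng = np.random.default_rng(seed)
    perm_pos = rng.integers(1, ceil_len + 1, size=(n_perm, m))
    perm_stat = np.median(perm_pos / ceil_len, axis=1)
    count = int(np.count_nonzero(perm_stat <= observed))
    p = (count + 1) / (n_perm + 1)
    return observed, float(p)


def concordance_matrix(samples: dict[str, pd.DataFrame],
                       metric: str = "counts") -> pd.DataFrame:
    """Pairwise Spearman correlation between samples over shared transcripts.

    Each sample is a DataFrame with columns ``transcript_id`` and either
    ``count`` (metric="counts") or ``mean_polya_length``
    (metric="mean_polya_length").  Pairs sharing fewer than 3 transcripts
    get NA; the diagonal is 1.
    """
    if metric not in ("counts", "mean_polya_length"):
        raise ValueError("metric must be 'counts' or 'mean_polya_length'")
    col = "count" if metric == "counts" else "mean_polya_length"
    names = list(samples)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    series = {n: samples[n].set_index("transcript_id")[col] for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = series[a].index.intersection(series[b].index)
            if len(shared) < 3:
                rho = float("nan")
            else:
                rho = spearmanr(series[a].loc[shared], series[b].loc[shared]).statistic
            mat.loc[a, b] = rho
            mat.loc[b, a] = rho
    return mat


def per_transcript_summary(class_data: pd.DataFrame,
                           read_transcripts: dict[str, str]) -> pd.DataFrame:
    """Per-transcript read count and mean tail length for concordance input."""
    df = class_data.copy()
    df["transcript_id"] = df["readname"].map(read_transcripts)
    df = df.dropna(subset=["transcript_id"])
    out = df.groupby("transcript_id").agg(
        count=("readname", "size"),
        mean_polya_length=("polya_length", "mean")).reset_index()
    return out


def tag_frequency_summary(segmentations_by_sample: dict[str, list]) -> pd.DataFrame:
    """Per-sample fraction of reads under each of the five QC tags."""
    rows = []
    for name, segs in segmentations_by_sample.items():
        if not segs:
            raise ValueError(f"sample {name} has no segmentations")
        tags = pd.Series([s.qc_tag for s in segs])
        frac = tags.value_counts(normalize=True)
        row = {"sample_name": name}
        for t in QC_TAGS:
            row[t] = float(frac.get(t, 0.0))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_name", *QC_TAGS])


# ---------------------------------------------------------------------------
# Optional figure helpers
# ---------------------------------------------------------------------------

def plot_positional_profile(profile: PositionalProfile, path) -> None:
    """Residue position vs tail length scatter for one transcript."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    colors = {"C": "tab:blue", "G": "tab:orange", "U": "tab:red"}
    for base, sub in profile.points.groupby("base"):
        ax.scatter(sub["position_nt"], sub["polya_length_nt"],
                   s=12, label=base, color=colors.get(base, "gray"))
    ax.set_xlabel("residue position from 3' end (nt)")
    ax.set_ylabel("poly(A) tail length (nt)")
    ax.set_title(profile.transcript_id)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_composition(summaries: list[CompositionSummary], path) -> None:
    """Per-sample bar chart of C/G/U residue frequencies."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [s.sample_name for s in summaries]
    x = np.arange(len(names))
    width = 0.25
    fig, ax = plt.subplots(figsize=(1.5 + len(names), 4))
    for off, base in zip((-width, 0, width), "CGU"):
        vals = [getattr(s, f"freq_{base}") for s in summaries]
        ax.bar(x + off, vals, width, label=base)
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel("fraction of classified reads")
    ax.legend(title="residue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
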
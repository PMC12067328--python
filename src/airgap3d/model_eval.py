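"""Checkpoint-selection metrics and evaluation.

Three complementary full-reference metrics compare a generated volume with
its ground truth:

* RE — relative error, ``sum |I_gen - I_real| / sum I_real`` over all voxels
  of a pair (lower is better; scale-free in the sense that
  ``RE(k * real, real) = |k - 1|``).
* PSNR — ``10 log10(MAX_V^2 / MSE)`` in dB with ``MAX_V = 255`` for 8-bit
  data; identical pairs have MSE 0 and are reported as infinity.
* SSIM — the global (single-window) structural-similarity index over the
  whole volume pair, in [-1, 1], with the standard stabilisers
  ``c1 = (0.01 MAX_V)^2`` and ``c2 = (0.03 MAX_V)^2``.

A saved generator is scored by the mean of each metric over the test pairs;
the checkpoint with the best average rank across (RE ascending, PSNR
descending, SSIM descending) is selected, ties broken toward the later
epoch.  A rank-sum rule is used because the three metrics are combined into
a single decision; an RE-only rule is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .volume_io import Volume3D

__all__ = [
    "MetricConfig", "MetricReport",
    "relative_error", "psnr", "ssim", "evaluate_checkpoints", "rank_checkpoints",
]


@dataclass
class MetricConfig:
    max_v: float = 255.0
    c1: float | None = None      # default (0.01 * max_v)^2
    c2: float | None = None      # default (0.03 * max_v)^2
    psnr_cap_db: float = math.inf

    def __post_init__(self) -> None:
        if self.c1 is None:
            self.c1 = (0.01 * self.max_v) ** 2
        if self.c2 is None:
            self.c2 = (0.03 * self.max_v) ** 2
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be > 0")


@dataclass
class MetricReport:
    checkpoint_id: str
    epoch: int
    re_mean: float
    psnr_mean_db: float
    ssim_mean: float
    n_pairs: int
    rank_sum: float | None = None
    selected: bool = False


def _data(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume3D) else v, dtype=np.float64)


def relative_error(gen, real) -> float:
    """Sum of absolute voxel differences normalised by the summed ground truth."""
    g, r = _data(gen), _data(real)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {r.shape}")
    denom = r.sum()
    if denom == 0:
        raise ValueError("relative error undefined for an all-zero ground truth")
    return float(np.abs(g - r).sum() / denom)


def psnr(gen, real, cfg: MetricConfig = MetricConfig()) -> float:
    """Peak signal-to-noise ratio in dB; identical pairs give the infinity sentinel."""
    g, r = _data(gen), _data(real)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {r.shape}")
    mse = float(((g - r) ** 2).mean())
    if mse == 0.0:
        return cfg.psnr_cap_db
    return 10.0 * math.log10(cfg.max_v ** 2 / mse)


def ssim(gen, real, cfg: MetricConfig = MetricConfig()) -> float:
    """Global single-window SSIM over the whole volume pair (symmetric)."""
    g, r = _data(gen), _data(real)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {r.shape}")
    mu_g, mu_r = g.mean(), r.mean()
    var_g, var_r = g.var(), r.var()
    cov = ((g - mu_g) * (r - mu_r)).mean()
    return float(
        (2 * mu_g * mu_r + cfg.c1) * (2 * cov + cfg.c2)
        / ((mu_g ** 2 + mu_r ** 2 + cfg.c1) * (var_g + var_r + cfg.c2))
    )


def evaluate_checkpoints(series, test_pairs, cfg: MetricConfig = MetricConfig(),
                         rule: str = "rank_sum"):
    """Score every checkpoint on the test pairs and select the best one.

    Parameters
    ----------
    series : CheckpointSeries or iterable of CheckpointEntry
        Saved generator models with epoch tags.
    test_pairs : sequence of TrainingPair
        Held-out (source, target) pairs; each checkpoint generates from the
        source and is compared against the target.
    rule : {"rank_sum", "re_only"}
        Selection rule; rank_sum averages the per-metric ranks.

    Returns
    -------
    (reports, selected) : (list of MetricReport, MetricReport)
    """
    from .cgan3d import generate  # deferred to avoid an import cycle

    entries = list(series)
    if not entries or not test_pairs:
        raise ValueError("need at least one checkpoint and one test pair")

    reports: list[MetricReport] = []
    for entry in entries:
        res, ps, ss = [], [], []
        for pair in test_pairs:
            gen_vol = generate(entry.model, pair.source)
            res.append(relative_error(gen_vol, pair.target))
            ps.append(psnr(gen_vol, pair.target, cfg))
            ss.append(ssim(gen_vol, pair.target, cfg))
        reports.append(MetricReport(
            checkpoint_id=f"generator_epoch{entry.epoch}",
            epoch=entry.epoch,
            re_mean=float(np.mean(res)),
            psnr_mean_db=float(np.mean(ps)),
            ssim_mean=float(np.mean(ss)),
            n_pairs=len(test_pairs),
        ))

    return rank_checkpoints(reports, rule)


def rank_checkpoints(reports: list[MetricReport], rule: str = "rank_sum"):
    """Assign rank sums and mark the selected checkpoint.

    RE ranks ascending (lower better), PSNR and SSIM descending; ties in the
    total are broken toward the later epoch.
    """
    if rule == "re_only":
        rank_sums = rankdata([r.re_mean for r in reports])
    elif rule == "rank_sum":
        rank_sums = (
            rankdata([r.re_mean for r in reports])            # ascending: low RE good
            + rankdata([-r.psnr_mean_db for r in reports])    # descending
            + rankdata([-r.ssim_mean for r in reports])       # descending
        )
    else:
        raise ValueError(f"unknown selection rule {rule!r}")

    best_idx = 0
    for i, r in enumerate(reports):
        r.rank_sum = float(rank_sums[i])
        r.selected = False
        # ties broken toward the later epoch
        if (r.rank_sum, -r.epoch) <= (reports[best_idx].rank_sum, -reports[best_idx].epoch):
            best_idx = i
    reports[best_idx].selected = True
    return reports, reports[best_idx]


def reports_to_frame(reports) -> pd.DataFrame:
    """Serialize MetricReports to a table (one row per checkpoint)."""
    return pd.DataFrame([{
        "checkpoint_id": r.checkpoint_id, "epoch": r.epoch, "re_mean": r.re_mean,
        "psnr_mean_db": r.psnr_mean_db, "ssim_mean": r.ssim_mean,
        "n_pairs": r.n_pairs, "rank_sum": r.rank_sum, "selected": r.selected,
    } for r in reports])
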
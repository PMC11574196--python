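"""Synthetic single-cell data generator.

Emulates the per-cell, per-frame tables that segmentation and tracking
tools export from heteroplasmy time-lapse experiments, on top of
ground-truth lineages produced by the array segregation model.  The
generator bridges the discrete synchronous generations of the simulator
to frame-resolution time:

* during each 1.5-h cycle a cell transfers its daughter's mtDNA
  allocation across the mother–bud neck over the first ~47.5 min (the
  content-exchange window) while replenishing its own copy number, so
  the mother dips below capacity and recovers within the cycle and the
  bud's copy number rises from zero to its allocation and on to
  capacity by division;
* each mtDNA variant drives synthesis of its fluorescent fusion
  protein, dP/dt = gain * copies - k * P, so fluorescence lags copy
  number with the measured turnover rate k = 0.31 / h ("fossil"
  protein); synthesis stops inside a chloramphenicol window;
* observed intensity is protein per cell volume, attenuated by
  photobleaching, plus Gaussian background (recorded separately, as if
  measured in cell-free areas) and multiplicative measurement noise;
* buds appear at cycle start, grow linearly to 55 % of the mother's
  volume at separation, and the bud-to-mother volume ratio is recorded
  for growth-stage matching.

Every observable is reproducible from (config, seed), and ground-truth
copy numbers always accompany the observable tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arrays
from .simulate import SimConfig


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    Defaults encode the study conditions: protein turnover 0.31 per
    hour, 15-min frame interval, 1.18 foci per 5-min window, 47.5-min
    content exchange, buds separating at 55 % of the mother volume.
    Gains, volumes and noise levels are free parameters of the
    emulation; see the methods note for the chosen values.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    protein_decay_k: float = 0.31  # per hour
    synthesis_gain: float = 40.0  # a.u. per copy per hour
    bg_mean_ng: float = 5.0  # a.u.
    bg_sd_ng: float = 0.5
    bg_mean_mkate: float = 5.0
    bg_sd_mkate: float = 0.5
    autofluor: float = 20.0  # cellular autofluorescence per channel, a.u. (per volume)
    photobleach_factor: float = 0.995  # per-frame multiplier
    noise_cv: float = 0.05
    frame_interval_min: float = 15.0
    mother_volume_fl: float = 40.0
    bud_volume_fraction: float = 0.55
    dropout_rate: float = 0.0  # per-division probability of total mtDNA loss
    cap_start_h: float | None = None
    cap_end_h: float | None = None
    foci_rate_per_5min: float = 1.18
    exchange_duration_min: float = 47.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_decay_k <= 0 or self.synthesis_gain < 0:
            raise ValueError("rates must be non-negative (decay strictly positive)")
        if not 0.0 < self.photobleach_factor <= 1.0:
            raise ValueError("photobleach_factor must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.frame_interval_min <= 0 or self.exchange_duration_min <= 0:
            raise ValueError("durations must be positive")


def generate_truth_lineage(
    config: GeneratorConfig,
    duration_h: float | None = None,
    rng: np.random.Generator | None = None,
    cell_prefix: str = "c",
) -> pd.DataFrame:
    """Ground-truth per-cell, per-frame copy counts of one lineage.

    Runs the array segregation model cycle by cycle and interpolates
    per-variant copy counts onto the imaging frame grid.  Returns one
    row per cell per frame with columns ``cell_id``, ``parent_id``,
    ``birth_generation``, ``frame``, ``time_h``, ``copies0``,
    ``copies1``, ``volume``, ``bud_ratio``.
    """
    sim = config.sim
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = sim.generation_hours
    if duration_h is None:
        duration_h = sim.n_generations * T
    n_cycles = max(1, math.ceil(duration_h / T - 1e-9))
    tau_ex = min(config.exchange_duration_min / 60.0, T)
    dt = config.frame_interval_min / 60.0
    n = sim.n_copies
    ndau = sim.ndau

    # cell bookkeeping: id -> (parent, birth_cycle, has_mtdna)
    parent: dict[str, str | None] = {}
    birth_cycle: dict[str, int] = {}
    has_mtdna: dict[str, bool] = {}
    start_arr: dict[str, np.ndarray] = {}  # array at capacity at current cycle start

    founder = f"{cell_prefix}0"
    parent[founder] = None
    birth_cycle[founder] = 0
    has_mtdna[founder] = True
    start_arr[founder] = sim.founder_array()
    next_idx = 1

    rows: list[dict] = []
    frames_all = np.arange(0.0, duration_h + 1e-9, dt)

    def frac1(arr: np.ndarray) -> float:
        return arrays.allele_fraction(arr) if arr.size else 0.0

    for g in range(n_cycles):
        t_lo, t_hi = g * T, (g + 1) * T
        frame_times = frames_all[(frames_all >= t_lo - 1e-9) & (frames_all <= min(t_hi, duration_h) + 1e-9)]
        events = []  # (mother, daughter, f_start, f_m_end, f_d_alloc, f_d_end, d_has_mtdna)
        next_start: dict[str, np.ndarray] = {}
        for m in sorted(start_arr):
            d = f"{cell_prefix}{next_idx}"
            next_idx += 1
            parent[d] = m
            birth_cycle[d] = g + 1
            if not has_mtdna[m]:
                has_mtdna[d] = False
                events.append((m, d, 0.0, 0.0, 0.0, 0.0, False))
                next_start[m] = np.empty(0, dtype=np.uint8)
                next_start[d] = np.empty(0, dtype=np.uint8)
                continue
            a0 = start_arr[m]
            shuffled = arrays.shuffle(a0, sim.nspl, rng)
            m_arr, d_arr = arrays.divide(shuffled, ndau)
            dropout = config.dropout_rate > 0 and rng.random() < config.dropout_rate
            has_mtdna[d] = not dropout
            m_next = arrays.replicate_to_capacity(m_arr, n, rng)
            d_next = (
                np.empty(0, dtype=np.uint8)
                if dropout
                else arrays.replicate_to_capacity(d_arr, n, rng)
            )
            events.append(
                (m, d, frac1(a0), frac1(m_next), frac1(d_arr), frac1(d_next), not dropout)
            )
            next_start[m] = m_next
            next_start[d] = d_next

        for m, d, f0, fm, fd0, fd1, d_ok in events:
            # the founder (zygote) is full-sized from the start; other cells
            # spend their first full cycle growing from bud size to maturity
            m_mature = birth_cycle[m] < g or m == founder
            for t in frame_times:
                tau = t - t_lo
                u = tau / T
                frame = int(round(t / dt))
                # mother compartment: dips during exchange, replenishes by cycle end
                if has_mtdna[m]:
                    c_m = n - ndau * min(tau / tau_ex, 1.0) + ndau * u
                    f_m = f0 + (fm - f0) * u
                else:
                    c_m, f_m = 0.0, 0.0
                v_m = config.mother_volume_fl if m_mature else config.mother_volume_fl * (
                    config.bud_volume_fraction + (1 - config.bud_volume_fraction) * u
                )
                bud_vol = config.bud_volume_fraction * config.mother_volume_fl * u
                rows.append(
                    {
                        "cell_id": m,
                        "parent_id": parent[m],
                        "birth_generation": birth_cycle[m],
                        "frame": frame,
                        "time_h": t,
                        "copies0": c_m * (1 - f_m),
                        "copies1": c_m * f_m,
                        "volume": v_m,
                        "bud_ratio": min(bud_vol / v_m, 1.0),
                    }
                )
                # bud: gains its allocation during the exchange window, then replicates
                if tau <= 0 or bud_vol <= 0:
                    continue
                if has_mtdna[m] and d_ok:
                    if tau < tau_ex:
                        c_d = ndau * (tau / tau_ex)
                    else:
                        c_d = ndau + (n - ndau) * (tau - tau_ex) / (T - tau_ex)
                    f_d = fd0 + (fd1 - fd0) * u
                else:
                    c_d, f_d = 0.0, 0.0
                rows.append(
                    {
                        "cell_id": d,
                        "parent_id": m,
                        "birth_generation": birth_cycle[d],
                        "frame": frame,
                        "time_h": t,
                        "copies0": c_d * (1 - f_d),
                        "copies1": c_d * f_d,
                        "volume": bud_vol,
                        "bud_ratio": np.nan,
                    }
                )
        start_arr = next_start
        if t_hi >= duration_h:
            break

    df = pd.DataFrame(rows)
    # a frame on a cycle boundary is emitted by both cycles; keep the later row
    df = df.drop_duplicates(subset=["cell_id", "frame"], keep="last").reset_index(drop=True)
    return df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)


def copies_to_intensity(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Render ground-truth copy counts into observable cell records.

    Each variant's fluorescent protein follows
    ``dP/dt = gain * copies - k * P`` (synthesis zero inside the
    chloramphenicol window), integrated exactly over each frame
    interval with the interval-mean copy number; protein starts at the
    steady state of the first observed copy number.  Observed intensity
    is protein / volume, scaled by ``photobleach_factor ** frame``,
    times multiplicative noise, plus a per-frame Gaussian background
    whose true value is recorded in the ``bg_*`` columns (the cell-free
    measurement).  Variant 1 reports in the mKate2 channel, variant 0
    in the NeonGreen channel.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    k = config.protein_decay_k
    s = config.synthesis_gain
    frames = np.sort(truth["frame"].unique())
    bg = {
        "ng": dict(zip(frames, rng.normal(config.bg_mean_ng, config.bg_sd_ng, frames.size))),
        "mkate": dict(
            zip(frames, rng.normal(config.bg_mean_mkate, config.bg_sd_mkate, frames.size))
        ),
    }

    def in_cap(t: float) -> bool:
        return (
            config.cap_start_h is not None
            and config.cap_end_h is not None
            and config.cap_start_h <= t <= config.cap_end_h
        )

    records = []
    for cell_id, grp in truth.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        t = grp["time_h"].to_numpy()
        copies = {"ng": grp["copies0"].to_numpy(), "mkate": grp["copies1"].to_numpy()}
        proteins = {}
        for ch in ("ng", "mkate"):
            c = copies[ch]
            P = np.empty_like(c)
            P[0] = 0.0 if in_cap(t[0]) else s * c[0] / k
            for i in range(1, c.size):
                delta = t[i] - t[i - 1]
                decay = math.exp(-k * delta)
                s_eff = 0.0 if in_cap((t[i] + t[i - 1]) / 2) else s
                cbar = 0.5 * (c[i] + c[i - 1])
                P[i] = P[i - 1] * decay + s_eff * cbar / k * (1.0 - decay)
            proteins[ch] = P
        vol = grp["volume"].to_numpy()
        fr = grp["frame"].to_numpy()
        bleach = config.photobleach_factor ** fr
        noise = {
            ch: 1.0 + config.noise_cv * rng.standard_normal(fr.size) if config.noise_cv > 0 else np.ones(fr.size)
            for ch in ("ng", "mkate")
        }
        # cellular autofluorescence adds to both channels and bleaches with the
        # signal; it is what keeps the homoplasmic h peaks away from 0 and 1
        i_ng = np.maximum(
            (proteins["ng"] / vol + config.autofluor) * bleach * noise["ng"], 0.0
        ) + np.array([bg["ng"][f] for f in fr])
        i_mkate = np.maximum(
            (proteins["mkate"] / vol + config.autofluor) * bleach * noise["mkate"], 0.0
        ) + np.array([bg["mkate"][f] for f in fr])
        for j in range(fr.size):
            records.append(
                {
                    "frame": int(fr[j]),
                    "time_h": float(t[j]),
                    "cell_id": cell_id,
                    "parent_id": grp["parent_id"].iloc[j],
                    "volume": float(vol[j]),
                    "i_ng": float(i_ng[j]),
                    "i_mkate": float(i_mkate[j]),
                    "bg_ng": float(bg["ng"][fr[j]]),
                    "bg_mkate": float(bg["mkate"][fr[j]]),
                    "bud_ratio": float(grp["bud_ratio"].iloc[j]),
                }
            )
    return pd.DataFrame(records).sort_values(["frame", "cell_id"], kind="mergesort").reset_index(drop=True)


def generate_cap_series(
    config: GeneratorConfig,
    duration_h: float = 6.0,
    n_replicates: int = 1,
    copies_per_variant: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Chloramphenicol-treatment fluorescence decay series.

    Synthesis is off for the whole series, so the per-volume signal of a
    non-dividing cell follows the closed form
    ``I(t) = A exp(-k t) + C`` with ``A = gain * copies / (k * volume)``
    and ``C`` the bottom plateau (cellular autofluorescence plus the
    channel background mean).  Multiplicative noise of the
    configured CV is applied when nonzero.  Returns a tidy table with
    columns ``replicate``, ``time_h``, ``channel``, ``intensity``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if copies_per_variant is None:
        copies_per_variant = config.sim.n_copies / 2
    t = np.arange(0.0, duration_h + 1e-9, config.frame_interval_min / 60.0)
    k = config.protein_decay_k
    A = config.synthesis_gain * copies_per_variant / (k * config.mother_volume_fl)
    rows = []
    for rep in range(n_replicates):
        for ch, bg_mean in (("ng", config.bg_mean_ng), ("mkate", config.bg_mean_mkate)):
            clean = A * np.exp(-k * t) + bg_mean + config.autofluor
            if config.noise_cv > 0:
                clean = clean * (1.0 + config.noise_cv * rng.standard_normal(t.size))
            for ti, yi in zip(t, clean):
                rows.append({"replicate": rep, "time_h": float(ti), "channel": ch, "intensity": float(yi)})
    return pd.DataFrame(rows)


def generate_foci_stream(
    config: GeneratorConfig,
    n_pairs: int = 93,
    n_windows: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Poisson counts of mtDNA foci crossing the bud neck per 5-min window.

    One independent Poisson draw at the configured rate per pair and
    window, mirroring the mother–bud pair observations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if config.foci_rate_per_5min < 0:
        raise ValueError("foci rate must be non-negative")
    rows = []
    for pair in range(n_pairs):
        for w in range(n_windows):
            rows.append(
                {
                    "pair_id": pair,
                    "window_index": w,
                    "crossings": int(rng.poisson(config.foci_rate_per_5min)),
                }
            )
    return pd.DataFrame(rows)


def generate_heteroplasmy_study(
    config: GeneratorConfig,
    n_populations: int = 9,
    duration_h: float = 8.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: observable records and matching ground truth.

    ``n_populations`` independent lineages from heteroplasmic founders
    are tracked over ``duration_h`` hours.  Returns
    ``(records, truth)``: the observable cell-record table (with a
    ``population`` column prepended) and the ground-truth copy-count
    table used to generate it.
    """
    rec_parts, truth_parts = [], []
    for p in range(n_populations):
        rng = np.random.default_rng(config.seed + 1009 * (p + 1))
        truth = generate_truth_lineage(config, duration_h=duration_h, rng=rng, cell_prefix=f"p{p}_c")
        records = copies_to_intensity(truth, config, rng=rng)
        truth = truth.assign(population=p)
        records = records.assign(population=p)
        rec_parts.append(records)
        truth_parts.append(truth)
    records = pd.concat(rec_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    truth["true_fraction"] = np.where(
        truth.copies0 + truth.copies1 > 0,
        truth.copies1 / (truth.copies0 + truth.copies1).replace(0, np.nan),
        np.nan,
    )
    cols = ["population"] + [c for c in records.columns if c != "population"]
    return records[cols], truth
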
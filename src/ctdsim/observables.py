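"""Readouts over simulated transcription: metagene profiles, amplicon
(ChIP-qPCR-like) signals, settling positions, and threshold-and-scale
fits of model profiles to measured ones.

The central quantity is the per-position ratio of phosphorylated repeats
to RNAPII: at each DNA site the number of phosphorylated repeats of the
occupying polymerase, divided by the number of repeats modelled, and
averaged over occupied observations only -- the per-polymerase
interpretation of a ChIP ratio track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctd_model import GeneConfig
from .sitegraph_engine import DefinitionError

__all__ = [
    "PositionSnapshot",
    "MetageneProfile",
    "Amplicon",
    "AmpliconSet",
    "AmpliconReadout",
    "ScaleFit",
    "make_observable",
    "extract_snapshot",
    "ensemble_profile",
    "settling_position",
    "chip_readout",
    "fit_scale",
    "apply_cross_reactivity",
    "NOT_SETTLED",
]

NOT_SETTLED = None

CHANNELS = ("rnapii", "ser2p_ratio", "ser5p_ratio", "ser7p_ratio")


@dataclass
class PositionSnapshot:
    """Occupancy and per-site phospho counts at one instant.

    ``occupied[i]`` is 0/1 for site i (elongation sites then pA sites);
    ``n_ser2p/n_ser5p/n_ser7p`` count phosphorylated repeats (0..R) of
    the polymerase at that site, zero where unoccupied.  Polymerases at
    the promoter and in the free pool are reported separately.
    """
    time: float
    occupied: np.ndarray
    n_ser2p: np.ndarray
    n_ser5p: np.ndarray
    n_ser7p: np.ndarray
    promoter_pool: int
    free_pool: int
    n_mrna: int


def _n_sites(gene: GeneConfig) -> int:
    return gene.n_elongation_sites + gene.n_polyA_sites


def make_observable(gene: GeneConfig):
    """Observable callable for the CTD model, for use with ``simulate``.

    The returned function maps a mixture to a flat vector laid out as
    [occ(S), ser2p(S), ser5p(S), ser7p(S), promoter_pool, free_pool,
    n_mRNA] with S = n_elongation_sites + n_polyA_sites.
    """
    S = _n_sites(gene)
    N = gene.n_elongation_sites
    repeats = gene.repeats
    site_names = [f"e{i}" for i in range(1, N + 1)] + \
        [f"pA{j}" for j in range(1, gene.n_polyA_sites + 1)]

    def observe(m):
        out = np.zeros(4 * S + 3)
        dna = m.agents[next(iter(m.by_sig["DNA"]))]
        bonds = dna.bonds
        agents = m.agents
        for idx, site in enumerate(site_names):
            b = bonds.get(site)
            if b is None:
                continue
            ag = agents[b[0]]
            st = ag.states
            out[idx] = 1.0
            out[S + idx] = sum(st[f"ser2{r}"] == "p" for r in repeats)
            out[2 * S + idx] = sum(st[f"ser5{r}"] == "p" for r in repeats)
            out[3 * S + idx] = sum(st[f"ser7{r}"] == "p" for r in repeats)
        prom = free = 0
        for aid in m.by_sig["RNAPII"]:
            ag = agents[aid]
            if ag.bonds.get("p") is not None:
                prom += 1
            elif ag.bonds.get("a") is None and ag.bonds.get("e") is None:
                free += 1
        out[-3], out[-2], out[-1] = prom, free, m.count("mRNA")
        return out

    observe.columns = (
        [f"occ_{s}" for s in site_names]
        + [f"ser2p_{s}" for s in site_names]
        + [f"ser5p_{s}" for s in site_names]
        + [f"ser7p_{s}" for s in site_names]
        + ["promoter_pool", "free_pool", "n_mrna"])
    observe.n_sites = S
    return observe


def extract_snapshot(mixture, gene: GeneConfig) -> PositionSnapshot:
    """Read occupancy and phospho counts off a mixture's RNAPII-DNA bonds."""
    S = _n_sites(gene)
    vec = make_observable(gene)(mixture)
    snap = PositionSnapshot(
        time=mixture.time,
        occupied=vec[:S].copy(),
        n_ser2p=vec[S:2 * S].copy(),
        n_ser5p=vec[2 * S:3 * S].copy(),
        n_ser7p=vec[3 * S:4 * S].copy(),
        promoter_pool=int(vec[-3]),
        free_pool=int(vec[-2]),
        n_mrna=int(vec[-1]))
    for arr in (snap.n_ser2p, snap.n_ser5p, snap.n_ser7p):
        if np.any(arr[snap.occupied == 0] != 0):
            raise DefinitionError("phospho signal at an unoccupied site")
        if np.any(arr > gene.n_repeats):
            raise DefinitionError("phospho count exceeds repeat number")
    return snap


@dataclass
class MetageneProfile:
    """Per-position RNAPII density and phospho-to-RNAPII ratios,
    averaged over an ensemble within a time window.

    Ratios are phospho counts per occupied observation divided by the
    number of repeats, hence in [0, 1]; sites never observed occupied
    carry NaN ratios and are flagged in ``n_obs``.
    """
    gene: GeneConfig
    position_nt: np.ndarray
    rnapii_density: np.ndarray
    ser2p_ratio: np.ndarray
    ser5p_ratio: np.ndarray
    ser7p_ratio: np.ndarray
    n_obs: np.ndarray                 # occupied observations per site
    n_runs: int = 0
    time_window: tuple = (0.0, 0.0)

    def channel(self, name: str) -> np.ndarray:
        mapping = {"rnapii": self.rnapii_density,
                   "ser2p": self.ser2p_ratio,
                   "ser5p": self.ser5p_ratio,
                   "ser7p": self.ser7p_ratio}
        try:
            return mapping[name.removesuffix("_ratio")]
        except KeyError:
            raise DefinitionError(f"unknown channel {name!r}") from None

    def elongation_only(self, values: np.ndarray) -> np.ndarray:
        return values[: self.gene.n_elongation_sites]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position_nt": self.position_nt,
            "rnapii": self.rnapii_density,
            "ser2p_ratio": self.ser2p_ratio,
            "ser5p_ratio": self.ser5p_ratio,
            "ser7p_ratio": self.ser7p_ratio,
            "n_obs": self.n_obs.astype(int),
        })


def apply_cross_reactivity(profile: "MetageneProfile",
                           matrix=None) -> "MetageneProfile":
    """Map true phospho ratios to antibody-observed signals.

    ``matrix`` is a 3x3 cross-reactivity matrix over (Ser2~P, Ser5~P,
    Ser7~P): observed_i = sum_j matrix[i, j] * true_j per site.  The
    default is the identity (ideal mark-specific antibodies); no
    measured weights are bundled, but ChIP antibodies are known to
    cross-react and this is the hook where calibrated weights enter.
    """
    import dataclasses
    if matrix is None:
        return profile
    M = np.asarray(matrix, float)
    if M.shape != (3, 3):
        raise DefinitionError("cross-reactivity matrix must be 3x3")
    true = np.vstack([profile.ser2p_ratio, profile.ser5p_ratio,
                      profile.ser7p_ratio])
    obs = M @ true
    return dataclasses.replace(
        profile, ser2p_ratio=obs[0], ser5p_ratio=obs[1],
        ser7p_ratio=obs[2])


def _window_mask(times, window):
    lo, hi = window
    return (times >= lo) & (times <= hi)


def ensemble_profile(trajectories, gene: GeneConfig,
                     time_window=None, windows=None) -> MetageneProfile:
    """Average snapshots over an ensemble into a metagene profile.

    ``time_window`` applies one (lo, hi) window to every trajectory;
    ``windows`` may instead give one window per trajectory (e.g. a
    per-run steady-state window from release events).
    """
    if not trajectories:
        raise DefinitionError("need at least one trajectory")
    if windows is None:
        if time_window is None:
            raise DefinitionError("a time window is required")
        windows = [time_window] * len(trajectories)
    S = _n_sites(gene)
    occ_sum = np.zeros(S)
    ph_sum = np.zeros((3, S))
    n_snap = 0
    for traj, win in zip(trajectories, windows):
        mask = _window_mask(traj.times, win)
        if not mask.any():
            continue
        v = traj.values[mask]
        if v.shape[1] < 4 * S:
            raise DefinitionError("trajectory does not carry site observables")
        n_snap += v.shape[0]
        occ_sum += v[:, :S].sum(0)
        for c in range(3):
            ph_sum[c] += v[:, (c + 1) * S:(c + 2) * S].sum(0)
    if n_snap == 0:
        raise DefinitionError("empty sampling window")
    R = gene.n_repeats
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = ph_sum / (R * occ_sum)
    ratios[:, occ_sum == 0] = np.nan
    pos = np.array([gene.site_start_nt(i) for i in range(1, S + 1)])
    lo = min(w[0] for w in windows)
    hi = max(w[1] for w in windows)
    return MetageneProfile(
        gene=gene, position_nt=pos,
        rnapii_density=occ_sum / n_snap,
        ser2p_ratio=ratios[0], ser5p_ratio=ratios[1], ser7p_ratio=ratios[2],
        n_obs=occ_sum, n_runs=len(trajectories), time_window=(lo, hi))


def _biexp_denoise(pos, y):
    """Least-squares projection of a profile onto c0 + c1 e^(-x/l1) +
    c2 e^(-x/l2), with the length scales searched on a log grid.

    A relaxation profile over the gene is a mixture of exponentials in
    elongation time (hence in position), so this projection denoises
    without biasing the shape; it uses every site to pin down the
    approach to the plateau, which a pointwise noisy curve cannot.
    """
    x = np.asarray(pos, float)
    best = None
    scales = np.geomspace(10.0, 2500.0, 28)
    for i, l1 in enumerate(scales):
        e1 = np.exp(-x / l1)
        for l2 in scales[i + 1:]:
            X = np.column_stack([np.ones_like(x), e1, np.exp(-x / l2)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ coef
            sse = float(r @ r)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, X @ coef)
    return best[1]


def settling_position(profile: MetageneProfile, channel: str,
                      tolerance: float = 0.05, plateau_sites: int = 10,
                      smooth: str | int = "biexp"):
    """Position (nt) at which a channel settles onto its 3' plateau.

    The plateau is the mean over the last ``plateau_sites`` elongation
    sites; the band is ``tolerance`` times the channel's maximum
    deviation from the plateau; the result is the start coordinate of
    the first site from which the channel stays inside the band.

    The all-later-sites band criterion is meaningless on a pointwise
    noisy curve (any late excursion pushes it 3'), so the profile is
    denoised first: ``smooth="biexp"`` (default) projects onto a
    two-exponential relaxation curve, an odd integer applies a running
    median of that width, and ``smooth=1`` tests the raw values.
    Returns ``NOT_SETTLED`` (None) if the channel never settles.
    """
    y = profile.elongation_only(np.asarray(profile.channel(channel), float))
    pos = profile.elongation_only(profile.position_nt)
    ok = np.isfinite(y)
    y, pos = y[ok], pos[ok]
    if len(y) < plateau_sites:
        raise DefinitionError(
            f"need at least {plateau_sites} trailing sites with data")
    if smooth == "biexp":
        if len(y) >= 8 and np.ptp(y) > 0:
            y = _biexp_denoise(pos, y)
    elif isinstance(smooth, int) and smooth > 1:
        from scipy.ndimage import median_filter
        y = median_filter(y, size=smooth, mode="nearest")
    plateau = y[-plateau_sites:].mean()
    dev = np.abs(y - plateau)
    band = tolerance * dev.max()
    inside = dev <= band
    if not inside[-1]:
        return NOT_SETTLED
    idx = len(y) - 1
    for i in range(len(y) - 1, -1, -1):
        if inside[i]:
            idx = i
        else:
            break
    return int(pos[idx])


# ----------------------------------------------------------------------
# Amplicon (ChIP-qPCR-like) readouts
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Amplicon:
    name: str
    start_nt: int
    end_nt: int                       # inclusive, 1-based

    def __post_init__(self):
        if self.start_nt < 1 or self.end_nt < self.start_nt:
            raise DefinitionError(f"bad amplicon interval {self.name!r}")


@dataclass(frozen=True)
class AmpliconSet:
    """Named nt intervals assayed along the gene."""
    amplicons: tuple

    @classmethod
    def default_for(cls, gene: GeneConfig, pause_nt: int | None = None):
        """Promoter, exon 1, around the 3' splice site, and exon 2 ends.

        Exact reporter coordinates are not fixed by the construct we
        emulate, so the defaults tile the gene: the 3'-splice-site
        amplicon is centred on ``pause_nt`` when given (the pause is
        splicing-associated), otherwise on the gene midpoint.
        """
        L = gene.coding_nt
        fp = gene.footprint_nt
        mid = pause_nt if pause_nt is not None else L // 2
        mid = min(max(mid, 2 * fp), L - 2 * fp)
        half = 2 * fp
        amps = (
            Amplicon("Prom", 1, min(3 * fp, L)),
            Amplicon("E1", max(1, mid // 2 - half), min(mid // 2 + half, L)),
            Amplicon("3SS", mid - half + 1, mid + half),
            Amplicon("5p-E2", mid + half + 1, min(mid + 3 * half, L)),
            Amplicon("3p-E2", max(1, L - 4 * fp + 1), L),
        )
        return cls(amps)

    def __iter__(self):
        return iter(self.amplicons)

    def site_indices(self, gene: GeneConfig):
        """0-based elongation-site indices overlapped by each amplicon."""
        out = {}
        fp = gene.footprint_nt
        for amp in self.amplicons:
            if amp.end_nt > gene.coding_nt:
                raise DefinitionError(
                    f"amplicon {amp.name!r} extends beyond the gene")
            first = (amp.start_nt - 1) // fp
            last = (amp.end_nt - 1) // fp
            out[amp.name] = list(range(first, last + 1))
        return out


@dataclass
class AmpliconReadout:
    """Induction-normalized per-amplicon signals over time.

    ``raw[channel][amplicon]`` is the ensemble-mean summed signal per
    requested time; ``normalized`` divides by the value at the
    reference time (series with zero reference signal are left NaN and
    listed in ``undefined``).  ``per_run`` keeps the per-trajectory raw
    sums for paired statistics.
    """
    amplicons: AmpliconSet
    times: np.ndarray
    reference_time: float
    raw: dict
    normalized: dict
    undefined: list
    per_run: dict                     # (channel, amplicon) -> (runs, times)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch, per_amp in self.raw.items():
            for amp, series in per_amp.items():
                for k, t in enumerate(self.times):
                    rows.append({
                        "time_s": t, "amplicon": amp, "channel": ch,
                        "raw": series[k],
                        "normalized": self.normalized[ch][amp][k]})
        return pd.DataFrame(rows)


def chip_readout(trajectories, gene: GeneConfig, amplicons: AmpliconSet,
                 times, reference_time) -> AmpliconReadout:
    """Sum occupancy / phospho counts over each amplicon's sites,
    ensemble-average at each requested time, and normalize to the
    reference time."""
    times = np.asarray(sorted(times), float)
    if reference_time not in times:
        raise DefinitionError("reference_time must be one of the readout times")
    S = _n_sites(gene)
    sites = amplicons.site_indices(gene)
    chan_slices = {"rnapii": slice(0, S), "ser2p": slice(S, 2 * S),
                   "ser5p": slice(2 * S, 3 * S)}
    n_runs = len(trajectories)
    per_run = {}
    for ch, sl in chan_slices.items():
        for amp, idx in sites.items():
            arr = np.zeros((n_runs, len(times)))
            for ri, traj in enumerate(trajectories):
                for k, t in enumerate(times):
                    where = np.where(np.isclose(traj.times, t))[0]
                    if len(where) == 0:
                        raise DefinitionError(
                            f"trajectory lacks a snapshot at t={t}")
                    row = traj.values[where[0]]
                    arr[ri, k] = row[sl][idx].sum()
            per_run[(ch, amp)] = arr
    raw = {ch: {} for ch in chan_slices}
    normalized = {ch: {} for ch in chan_slices}
    undefined = []
    ref_k = int(np.where(np.isclose(times, reference_time))[0][0])
    for (ch, amp), arr in per_run.items():
        series = arr.mean(0)
        raw[ch][amp] = series
        ref = series[ref_k]
        if ref <= 0:
            normalized[ch][amp] = np.full_like(series, np.nan)
            undefined.append((ch, amp))
        else:
            normalized[ch][amp] = series / ref
    return AmpliconReadout(
        amplicons=amplicons, times=times, reference_time=reference_time,
        raw=raw, normalized=normalized, undefined=undefined,
        per_run=per_run)


# ----------------------------------------------------------------------
# Threshold-and-scale fit
# ----------------------------------------------------------------------

@dataclass
class ScaleFit:
    """measured ~ scale * max(model - floor, 0) + offset."""
    scale: float
    offset: float
    floor: float
    sse: float
    degenerate: bool = False

    def predict(self, model_values):
        x = np.maximum(np.asarray(model_values, float) - self.floor, 0.0)
        return self.scale * x + self.offset


def fit_scale(model_profile, measured_profile,
              floor_quantiles=None) -> ScaleFit:
    """Least-squares threshold-and-scale fit of a model channel to a
    measured one.

    The floor is searched over a coarse grid of model quantiles; for
    each floor the scale and offset are solved in closed form.  A
    constant model vector leaves the scale unidentifiable: the fit
    degenerates to offset-only and is flagged.
    """
    y = np.asarray(measured_profile, float)
    m = np.asarray(model_profile, float)
    ok = np.isfinite(y) & np.isfinite(m)
    y, m = y[ok], m[ok]
    if len(y) < 3 or len(y) != len(m):
        raise DefinitionError("need >= 3 aligned finite points")
    if np.ptp(m) == 0.0:
        off = float(y.mean())
        return ScaleFit(scale=0.0, offset=off, floor=0.0,
                        sse=float(((y - off) ** 2).sum()), degenerate=True)
    if floor_quantiles is None:
        floor_quantiles = np.linspace(0.0, 0.8, 17)
    floors = np.unique(np.concatenate(
        [[0.0], np.quantile(m, floor_quantiles)]))
    best = None
    for floor in floors:
        x = np.maximum(m - floor, 0.0)
        if np.ptp(x) == 0.0:
            continue
        X = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best.sse - 1e-12:
            best = ScaleFit(scale=float(coef[0]), offset=float(coef[1]),
                            floor=float(floor), sse=sse)
    return best
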
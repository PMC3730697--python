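"""Calibration utility for the unprinted transcription-cycle rates.

The CTD model's phosphorylation tiers (p0, p0/2, p0/10, p3) are fixed,
but the elongation step rate, the promoter-loading rate and the enzyme
copy numbers are free.  This script documents and reproduces how the
shipped defaults were chosen against three observable targets:

  (a) steady-state mature-mRNA release interval ~ 4 s;
  (b) Ser5~P-to-RNAPII ratio settling ~ 750 nt from the TSS;
  (c) Ser2~P-to-RNAPII ratio plateau ~ 1000 nt from the TSS.

Stage 1 screens enzyme copy numbers with a per-repeat continuous-time
Markov-chain proxy of the elongation-phase phospho-state (fast; no
stochastic simulation), looking for a Ser2:Ser5 settling-position ratio
near 4:3.  Stage 2 refines the elongation step rate and the
promoter-loading rate by direct ensemble simulation under the same
settling estimator used by the analysis code.

Run:  python scripts/calibrate.py [--runs 200] [--seed 9000]
"""

import argparse
from dataclasses import replace

import numpy as np
from scipy.linalg import expm

import ctdsim
from ctdsim import RateConfig, SimConfig


def repeat_ctmc_steady_state(copies, rates: RateConfig):
    """Per-repeat elongation-context chain over (Ser2, Ser5) states
    [up, uu, pp, pu]; effective rates are binding tiers times free
    enzyme copies (release at p3 is fast and not rate-limiting)."""
    a = copies.rtr1 * rates.rtr1_bind
    b = (copies.ctk1 + copies.bur1) * rates.phosph1
    c = copies.ctk1 * rates.phosph1        # FROM_UU Ser5 kinase
    d = copies.fcp1 * rates.phosph1
    Q = np.zeros((4, 4))
    Q[0, 1], Q[0, 2] = a, b
    Q[1, 0] = c
    Q[2, 3], Q[2, 0] = a, d
    Q[3, 1] = d
    for i in range(4):
        Q[i, i] = -Q[i].sum()
    return Q


def proxy_profiles(copies, rates, ke, n_sites=80, t_hi=80.0):
    """Ser5~P / Ser2~P ratio curves over sites, averaging the chain
    over the Erlang age distribution a polymerase has at each site."""
    from scipy.stats import gamma
    Q = repeat_ctmc_steady_state(copies, rates)
    tg = np.linspace(0.01, t_hi, 1600)
    P = np.array([np.array([1.0, 0, 0, 0]) @ expm(Q * t) for t in tg])
    s5, s2 = P[:, 0] + P[:, 2], P[:, 2] + P[:, 3]
    dt = tg[1] - tg[0]
    out5, out2 = np.empty(n_sites), np.empty(n_sites)
    for i in range(1, n_sites + 1):
        w = gamma.pdf(tg, a=i, scale=1.0 / ke)
        w /= max(w.sum() * dt, 1e-12)
        out5[i - 1] = (w * s5).sum() * dt
        out2[i - 1] = (w * s2).sum() * dt
    return out5, out2


def measure(config: SimConfig, n_runs, base_seed, t_max=240.0):
    prof = ctdsim.run_metagene(config, n_runs=n_runs, base_seed=base_seed,
                               t_max=t_max)
    rate = ctdsim.run_synthesis_rate(config, duration=150.0, burn_in=60.0,
                                     n_runs=8, base_seed=base_seed + 7)
    return (ctdsim.settling_position(prof, "ser2p"),
            ctdsim.settling_position(prof, "ser5p"),
            rate.mean_interval)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--runs", type=int, default=200)
    ap.add_argument("--seed", type=int, default=9000)
    ap.add_argument("--ke", type=float, nargs="*", default=None,
                    help="elongation step rates to profile")
    args = ap.parse_args()

    base = SimConfig()
    print("# stage 1: per-repeat chain proxy at shipped copy numbers")
    s5, s2 = proxy_profiles(base.copies, base.rates,
                            base.rates.elongation_step)
    print(f"proxy steady state: ser5p={s5[-10:].mean():.3f} "
          f"ser2p={s2[-10:].mean():.3f}")

    print("# stage 2: ensemble refinement of the elongation step rate")
    kes = args.ke or [base.rates.elongation_step]
    for ke in kes:
        cfg = base.replace(rates=replace(base.rates, elongation_step=ke,
                                         maturation_step=ke))
        x2, x5, interval = measure(cfg, args.runs, args.seed)
        print(f"ke={ke:g}: ser2p settles at {x2} nt, ser5p at {x5} nt, "
              f"release interval {interval:.2f} s "
              f"(targets: 1000 / 750 / 4)")


if __name__ == "__main__":
    main()
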
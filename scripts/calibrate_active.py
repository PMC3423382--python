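"""Verify (and document) the calibration of the default active parameter set.

The active Morris-Lecar-type parameters shipped as
``dcacrm.dynamics.DEFAULT_ACTIVE`` were obtained by a constrained search in
three stages:

1. Soma (plateau channels off): grid search over (G_Na, G_K,S, n_S rate)
   for repetitive Hopf-mediated spiking with rheobase well below the ramp
   peak, no depolarization block below I_S = 3, and a spike width of a few
   time units so that spike energy lies in the frequency band where the
   dendritic capacitance (set by VA_SD^AC) filters differentially.
2. Dendrite (closed form): the spikes-blocked equilibrium branch
   I_S(V_D) is available analytically, so (G_Ca, m_D half/slope, G_K,D,
   n_D half/slope) were chosen to give an S-shaped branch with onset fold
   between rheobase and the ramp peak and deactivation fold below
   rheobase.
3. Kinetics: the PIC activation time constant tau_mD(V) is bell-shaped --
   slowest near half-activation (delayed plateau onset, TTP > 0), fast far
   from it (prompt deactivation under a hyperpolarizing pulse).

Running this script re-checks every calibration constraint and prints a
report; it is a consistency gate, not a fitting run.

Usage: python scripts/calibrate_active.py
"""

from __future__ import annotations

import sys

import numpy as np

from dcacrm.bifurcation import dendritic_fold_currents, hopf_current, plateau_threshold
from dcacrm.dynamics import (
    DEFAULT_ACTIVE,
    resting_state,
    simulate,
    switching_protocol,
    triangular_protocol,
)
from dcacrm.firing import analyze, detect_spikes
from dcacrm.reduction import DEFAULT_PROPERTIES, solve_passive

CHECKS = []


def check(name, ok, detail=""):
    CHECKS.append((name, bool(ok)))
    print(f"[{'ok' if ok else 'FAIL'}] {name}" + (f"  ({detail})" if detail else ""))


def main():
    props = DEFAULT_PROPERTIES
    act = DEFAULT_ACTIVE
    variants = {va: solve_passive(props.replace(va_sd_ac=va)) for va in (0.08, 0.49, 0.88)}
    pp = variants[0.49]

    rest = resting_state(pp, props.p, act)
    check("rest near V_S = -0.5", abs(rest[0] + 0.5) < 0.05, f"V_S = {rest[0]:.3f}")

    hopfs = {va: hopf_current(ppv, props.p, act, i_range=(0.2, 1.5), coarse=27)
             for va, ppv in variants.items()}
    spread = max(hopfs.values()) - min(hopfs.values())
    check("Hopf (rheobase) invariant across VA_SD^AC", spread < 0.01,
          f"{ {k: round(v, 4) for k, v in hopfs.items()} }")

    blocked = act.replace(g_na=0.0, g_k_s=0.0)
    folds = dendritic_fold_currents(pp, props.p, blocked)
    check("dendritic branch is S-shaped", folds is not None, f"folds = {folds}")
    if folds:
        check("onset fold between rheobase and ramp peak",
              hopfs[0.49] < folds[0] < 2.5, f"onset = {folds[0]:.3f}")
        check("deactivation fold below rheobase",
              folds[1] < hopfs[0.49], f"offset = {folds[1]:.3f}")

    blocked_th = {va: plateau_threshold(ppv, props.p, blocked, n=31)
                  for va, ppv in variants.items()}
    check("blocked plateau threshold capacitance-invariant",
          max(blocked_th.values()) - min(blocked_th.values()) < 1e-3,
          f"{ {k: round(v, 4) for k, v in blocked_th.items()} }")

    proto = triangular_protocol()
    labels, thresholds = {}, {}
    for va, ppv in variants.items():
        tr = simulate(ppv, props.p, act, proto, dt_out=0.1)
        m = analyze(tr)
        labels[va] = (m.label, round(m.ttp, 1), round(m.tes, 1), round(m.dsf, 4))
        thresholds[va] = float(proto.current(m.plateau_onset_time))
    check("Type IV at all three VA_SD^AC variants",
          all(v[0] == "IV_bistable" for v in labels.values()), f"{labels}")
    check("dynamic plateau threshold decreases with VA_SD^AC",
          thresholds[0.08] > thresholds[0.49] > thresholds[0.88],
          f"{ {k: round(v, 3) for k, v in thresholds.items()} }")

    sw = switching_protocol()
    tr = simulate(pp, props.p, act, sw, dt_out=0.1)
    sp = detect_spikes(tr)
    n = lambda t0, t1: int(((sp >= t0) & (sp < t1)).sum())
    check("pulse switching rest -> firing -> rest",
          n(100, 600) == 0 and n(950, 1800) > 10 and n(2100, sw.t_end) == 0,
          f"spikes pre/mid/post = {n(100, 600)}/{n(950, 1800)}/{n(2100, sw.t_end)}")

    failed = [nm for nm, ok in CHECKS if not ok]
    print(f"\n{len(CHECKS) - len(failed)}/{len(CHECKS)} calibration constraints satisfied")
    return 1 if failed else 0


if __name__ == "__main__":
    sys.exit(main())
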
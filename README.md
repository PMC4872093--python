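# ispkit

Analysis toolkit for DNA target recognition by **Type ISP
restriction–modification enzymes** — single-polypeptide enzymes (prototypes
LlaGI and LlaBIII from *Lactococcus lactis*) that combine a nuclease, a
helicase-like ATPase motor, an N6-adenine methyltransferase (MTase) and a
target recognition domain (TRD). The MTase–TRD unit clamps a short
asymmetric target (LlaGI: 5'-CTnGAyG-3'), bends and unwinds the duplex,
flips the target adenine into the MTase pocket, and reads the remaining
bases through hydrogen bonds from a small set of structurally conserved
loops. After recognition, the ATPase translocates downstream DNA at a
measurable stepping rate.

The package is written for structural biologists and enzymologists who want
to reproduce or extend this style of analysis on their own complexes,
alignments and stopped-flow data. It provides:

* **`struct_io`** — PDB/mmCIF reading (via gemmi), a light structure model,
  and the *target frame*: the methylated T:A pair is position **+1**,
  downstream positions are positive, upstream negative, with no position 0.
* **`contacts`** — protein–DNA hydrogen-bond detection (donor/acceptor heavy
  atoms within 3.5 Å), water-mediated bridges, side-chain intercalation into
  the base-stack cavity, and schematic contact tables.
* **`geometry`** — helical-axis fitting, bend angle between duplex arms,
  cross-strand phosphate groove widths, per-step twist, flipped-base
  detection.
* **`compare`** — Kabsch superposition, inter-domain rotation angles,
  global-alignment percent identity (BLOSUM62, end gaps free).
* **`msa`** — sequence-weighted conservation profiles and
  average-product-corrected mutual information (MI-APC) couplings with a
  per-residue coupling strength, top-fraction selection and hypergeometric
  contact enrichment.
* **`recognition`** — the residue ↔ target-base *recognition code*: mapping
  anchor positions across homologues, scoring residue/base-pair
  associations, and predicting targets from anchor residues.
* **`kinetics`** — triplex-displacement lag-phase fitting and the
  translocation (stepping) rate from lag time versus distance.
* **`synthetic`** — generators with planted ground truth (reduced-atom
  B-DNA, alignments, kinetic traces) that back the whole test suite.

## Core models

**Translocation kinetics.** A fluorescent triplex bound `d` bp downstream of
the target is displaced when the translocating enzyme arrives. Each trace
is fitted to a lag-phase model

```
Y(t) = m t                                  t <  T_app
Y(t) = A (1 − e^(−k (t − T_app))) + C1      t ≥  T_app,   C1 = m T_app
```

and the lag times follow `T_app = d / k_step + C2`; the slope of the
lag–distance line gives the stepping rate `k_step` (bp/s). `C2` is reported
but never interpreted as an initiation time.

**Couplings.** For alignment columns *i, j*, `MI(i,j)` is computed from
Henikoff-weighted joint frequencies (pseudocount, gaps as a 21st symbol)
and corrected as `MI_APC(i,j) = MI(i,j) − MI(i,·) MI(·,j) / MI(avg)`.
A residue's coupling strength is its summed share of the top-L couplings
(L = number of scored columns).

**Recognition code.** For anchor position *a*, residue *r* and oriented
base pair *b* at target position *p*, the association score is the product
of conditional purities `P(r | b) · P(b | r)` over enzymes that specify
*p*; entries with score ≥ 0.8 and ≥ 2 supporting enzymes form the code.

## Worked example

```python
import numpy as np
from ispkit import synthetic as syn, kinetics as K, struct_io as sio, geometry as geo

# --- translocation rate from noisy synthetic displacement traces
spec = syn.TraceSpec(distances=(500, 1000, 1500, 2000, 2500),
                     k_true=226.0, c2=5.0, noise_sd=0.02, seed=11)
traces = syn.simulate_traces(spec)
rate, fits = K.fit_traces_to_rate(traces)
for tr, f in zip(traces, fits):
    print(f"d = {tr.distance:6.0f} bp   T_app = {f.t_app:6.2f} s")
print(f"k_step = {rate.k_step:.1f} +/- {rate.k_step_se:.1f} bp/s   C2 = {rate.c2:.2f} s")

# --- bend angle of a duplex with a 34 degree kink planted at the target
model, truth = syn.make_duplex(syn.DuplexSpec(
    sequence="GCTAGCTAGCATCGATCGATCGATGCAT", kink=(13, 34.0)))
frame = sio.assign_target_frame(model, "N" * 28, ("D", 14, ""), target_start=-13)
bend = geo.bend_angle(model, frame, upstream=(-13, -2), downstream=(3, 14))
print(f"bend = {bend:.1f} deg (planted {truth.bend_angle:.0f})")
```

prints

```
d =    500 bp   T_app =   7.17 s
d =   1000 bp   T_app =   9.34 s
d =   1500 bp   T_app =  11.56 s
d =   2000 bp   T_app =  13.85 s
d =   2500 bp   T_app =  16.03 s
k_step = 224.9 +/- 1.1 bp/s   C2 = 4.92 s
bend = 34.0 deg (planted 34)
```

The lag times grow linearly with distance; inverting the slope recovers the
224.9 bp/s stepping rate (truth: 226 bp/s) with the 2% trace noise
propagated into a ±1.1 bp/s standard error, and the intercept returns the
planted 5 s offset. The kinked-duplex arms meet at 34.0°, matching the
planted deformation.

A command-line entry point wraps the same stages:

```sh
ispkit simulate --seed 3 --out bundle        # synthetic duplex, MSA, traces
ispkit report --config config.yaml --out out # contacts/geometry/msa/kinetics
```

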
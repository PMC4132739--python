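# txroadblock

Stochastic and analytic modeling of **transcriptional roadblocking**:
what happens when elongating RNA polymerase (RNAP) runs into a
sequence-specific DNA-binding protein sitting in its path.

The reference system is the *E. coli* lac repressor (LacI) bound at a lac
operator downstream of a constitutive promoter.  The package is for
quantitative/systems biologists who want to simulate or fit this kind of
system: it predicts the **readthrough fraction** `Rf` (transcription
downstream of the roadblock with the protein present, divided by
transcription with it absent) as a function of five control knobs —
promoter firing rate `k_F`, roadblocker binding rate `k_B`
(concentration × on-rate), unbinding rate `k_U` (operator affinity),
termination rate of paused RNAP `k_T` (Mfd-dependent), and
promoter–roadblock spacing.

## The model

RNAPs occupy 30 bp footprints on the promoter–spacer–operator lattice and
advance at 40 bp/s with hard-core exclusion.  An RNAP reaching the bound
roadblocker pauses; a paused RNAP is either terminated (`k_T`), resumes
after spontaneous roadblocker unbinding (`k_U`, "escape"), or actively
dislodges the roadblocker — at `k_SD` when alone, at `k_MD` when trailing
RNAPs are queued in contact (RNAP cooperation).  At negligible flux the
model collapses to the closed form

    Rf = k_U/(k_B+k_U) + k_B/(k_B+k_U) · (k_SD+k_U)/(k_SD+k_U+k_T)

(avoidance + pause resolved before termination), which doubles as the
independent oracle for the simulator.  Every pass is attributed to one
mechanism — single/multiple dislodgement, escape, absence, occlusion, or
facilitated absence — and the simulator tracks promoter *clogging*:
stalled queues reaching back over the promoter and blocking initiation.

A simulated-annealing fitter infers `(k_T, k_SD, k_MD)` from tabulated
`Rf` measurements, and a synthetic-data generator reproduces the
reporter-assay design grid (15 promoters over a 611-fold firing-rate
range, three operators, five repressor concentrations, three spacers, two
genotypes, 9 replicates) so the whole pipeline is testable end to end.

## Worked example

```python
from txroadblock.kinetics import KineticParams, K_U_OID
from txroadblock.analytic import low_flux_readthrough
from txroadblock.sim import SimConfig, simulate, readthrough_fraction

# ideal operator, 250 nM repressor, fitted rates
params = KineticParams(k_F=3.3e-4, k_B=0.6275, k_U=K_U_OID,
                       k_T=0.066, k_SD=0.0015, k_MD=0.026)

print(low_flux_readthrough(params))          # 0.02922829876863253
cfg = SimConfig(params=params, target_fires=30000, seed=17,
                record_events=True)
print(readthrough_fraction(cfg))             # 0.02849398386883512
res = simulate(cfg)
print(res.mechanism_fractions()["SD"])       # 0.7169373549883991
print(readthrough_fraction(
    SimConfig(params=params.replace(k_F=0.2), target_fires=20000,
              seed=8)))                      # 0.25674962624219505
```

At the weakest promoter (one firing every ~50 min) the simulated
readthrough (~2.9%) matches the closed form, and ~72% of the transcripts
that get past the roadblock do so because a lone paused RNAP actively
dislodged the repressor.  At the strongest promoter (`k_F = 0.2`)
cooperation between queued RNAPs lifts readthrough to ~26%.

The same runs from a shell:

```
txroadblock analytic --k-b 0.6275 --k-u 1.0 --k-t 0.063 --k-sd 0.0063
# Rf = 0.977279   (fast-unbinding regime: roadblocking nearly eliminated)
txroadblock synth --promoters 15 --seed 1 --out rf.tsv
txroadblock fit --table rf.tsv --seed 2 --out fit.tsv
```

See `docs/methods.md` for the model assumptions, attribution rules,
fitting design and limitations.

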
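# isletquant

Quantification of β-cell functional development from volumetric calcium
imaging, with a ground-truthed synthetic-islet generator.

## The problem

During zebrafish development (48–72 hpf), pancreatic β-cells acquire
glucose responsiveness in two waves that spread from the islet's outer
layer (the *mantle*) to its interior (the *core*), coordinated by islet
vascularization.  The functional readout per cell is the maximal
fractional calcium response to a 20 mM glucose challenge,

    Max ΔF/F0 = max_t (F(t) − F0) / F0,

with `F0` the fluorescence at the first time point.  A cell is
*glucose-responsive* when its Max ΔF/F0 clears a threshold within 3 min
of stimulation.  The cultured mouse-islet arm of the same study measures
glucose-stimulated insulin secretion (GSIS) sequentially at 3 mM then
20 mM glucose and summarises it as the Glucose Stimulation Index
GSI = high/low, plus whole-islet ("ensemble") calcium amplitudes under a
0.5 → 2.8 → 16.7 mM protocol.

`isletquant` implements the full quantification chain for volumetric
time-lapse recordings — cell detection, per-cell trace extraction,
ΔF/F0 and responsiveness calls, mantle/core stratification, vessel
proximity, synchrony, glucose-penetration modelling, GSIS/GSI and
ensemble-calcium analysis, and the study's statistics (Student t,
ANOVA + Dunnett, star annotation) — together with a forward model that
simulates all of these data types with known ground truth, so the
pipeline is validated by round-trip parameter recovery.  It is aimed at
imaging groups who need a tested, reusable reference implementation of
this analysis and a simulator to benchmark their own variants.

## Worked example

```python
import isletquant as iq

# simulate one 72 hpf wild-type islet with ground truth, image it,
# and re-quantify it blind
preset = iq.get_preset("wt_72hpf")
result = iq.run_islet(preset, seed=1, islet_id=1)

print("cells true/detected:", result.geometry.n_cells,
      len(result.detection.rois))
calls = result.calls
print("responsive cells:", int(calls.responsive.sum()))
print("core responsive :", int(calls[calls.compartment == 'core']
                               .responsive.sum()))
amp = 100 * calls.loc[calls.responsive, "max_dff"].mean()
print(f"mean Max dF/F0 : {amp:.1f}%")
```

Output:

```
cells true/detected: 23 22
responsive cells: 10
core responsive : 4
mean Max dF/F0 : 134.4%
```

One islet drew 23 cells (population mean 21.88 ± 3.4), detection found
22 of them, 10 were called glucose-responsive (population expectation
11.4), four of those in the core, and the mean recovered amplitude was
134% — one sample from the 145.6% ± 30% stage distribution.  Averaging
over 16 such islets recovers the stage parameters within sampling error;
that is exactly what the acceptance script does.

The same operations are scriptable from the shell:

```bash
isletquant simulate --preset wt_72hpf --seed 1 --out sim/
isletquant segment sim/recording.tif --diameter 7 --out rois.tsv
isletquant quantify sim/recording.tif --out calls.csv
isletquant stratify rois.tsv --voxel-size 3.5 0.8 0.8 --out comp.csv
isletquant gsis secretion.csv --out summary.csv
```

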
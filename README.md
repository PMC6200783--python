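# choroflow

Visualization and quantification of middle/large choroidal blood flow from
swept-source OCT angiography (SS-OCTA) en-face slabs.

## The problem

OCTA detects blood flow as the decorrelation between repeated OCT scans:
stationary tissue is dark, flow is bright. In en-face slabs of the
mid-choroid, however, the large choroidal vessels appear *dark* and the
surrounding stroma *bright* — the stromal brightness is not flow, but a
projection artifact of the dense choriocapillaris (CC) lying just beneath
the retinal pigment epithelium (RPE). `choroflow` removes that artifact and
quantifies the unveiled choroidal flow pattern. It is aimed at retinal
imaging researchers working with device-exported en-face slab images.

## The method

Two 30 µm slabs are taken below the outer RPE surface: the
choriocapillaris slab at 30–60 µm, and a *half-choroid* (HC) slab centred at
one half of the subfoveal choroidal thickness (SCT, the RPE-to-sclera
distance at the fovea; eyes with SCT < 150 µm are excluded). Three 8-bit
saturating subtractions (a ⊖ b = max(a − b, 0), the ImageJ "Subtract"
semantics) remove the artifact:

    sub_A = CC ⊖ HC,   sub_B = HC ⊖ sub_A,   final = HC ⊖ sub_B

which collapses algebraically to

    final = min( max(CC − HC, 0), HC ).

Stroma no brighter than the CC is removed exactly (final = 0); vessel lumina
whose stromal surround is at least twice as bright are recovered exactly
(final = HC). The final image is binarized with Bernsen's auto local
threshold (circular neighborhood, low-contrast fallback), the optic disc is
excluded with an oval mask on wide-field scans, and the **flow-area ratio**
is reported as 100 · (flow pixels) / (analyzed pixels). Cohort utilities
compute descriptive statistics and the Spearman rank correlation ρ between
SCT and flow-area ratio. A phantom generator (uniform CC layer, random-walk
vessel tubes, multiplicative projection artifact, additive noise, and a
spectral-domain attenuation mode in which no signal reaches the deep
choroid) provides ground truth for every stage.

## Worked example

```python
import choroflow as cf

# phantom eye at the default study conditions, fixed seed
eye = cf.generate_phantom_eye(cf.PhantomParams(seed=7))
res = cf.quantify_eye(eye.cc, eye.hc)
print(f"true lumen fraction : {100 * eye.truth.lumen_mask.mean():.1f} %")
print(f"measured flow area  : {res.ratio_pct:.1f} %")
print(f"Dice vs ground truth: {cf.dice_coefficient(res.flow_mask, eye.truth.lumen_mask):.3f}")

# the packaged 61-eye normal cohort
summary = cf.summarize(cf.filter_eligible(cf.load_reference_cohort()))
print(f"cohort: {summary.n_eyes} eyes / {summary.n_cases} cases")
print(f"flow area {summary.flow_pct.mean:.1f} +/- {summary.flow_pct.sd:.1f} % "
      f"(range {summary.flow_pct.min}-{summary.flow_pct.max})")
print(f"Spearman rho = {summary.spearman_rho:.3f}, p = {summary.spearman_p:.1e}")
```

prints

```
true lumen fraction : 25.1 %
measured flow area  : 26.2 %
Dice vs ground truth: 0.979
cohort: 61 eyes / 45 cases
flow area 27.3 +/- 8.2 % (range 11.5-50.1)
Spearman rho = 0.735, p = 1.6e-11
```

The phantom's measured flow area tracks the true vessel fraction to about a
percentage point, and the binarized flow mask overlaps the ground-truth
lumen map with Dice 0.98. In the reference cohort, thicker choroids carry a
larger flow area (ρ = 0.735): the flow-area ratio rises about fourfold from
the thinnest (180 µm, 11.5 %) to the thickest (500 µm, 45.1 %) choroid.

The same stages are available from the shell:

```sh
choroflow simulate --n-eyes 30 --seed 7 --out-dir sim/
choroflow subtract --cc sim/eye000_cc.tif --hc sim/eye000_hc.tif --out-dir out/
choroflow quantify --cc sim/eye000_cc.tif --hc sim/eye000_hc.tif --out report.json
choroflow cohort-stats --table sim/cohort.csv --out summary.json --plot scatter.png
```

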
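# bmfqsar

QSAR tools for predicting the **dietary biomagnification factor of organic
chemicals in fish** on the lipid-normalized log scale (Log BMF_L), for
environmental chemists and risk assessors working on bioaccumulation (the
B of PBT assessment).

The biomagnification factor is the steady-state concentration ratio between
a predator and its diet; normalized by the lipid content of both
(BMF_L = BMF · L_diet / L_fish) it becomes the endpoint modelled here, and a
chemical with BMF_L > 1 (Log BMF_L > 0) is classed as a biomagnifier.

The package provides, end to end:

* **Structure handling** — SMILES parsing, salt stripping, nitro
  standardization and canonicalization (RDKit-backed), plus CSV dataset
  curation with replicate averaging and quality labels (high/medium/low).
* **A from-scratch 2D descriptor engine** for the 17 descriptors used by the
  models: Broto–Moreau/Moran/Geary autocorrelations (AATS5i, MATS1i, GATS5m,
  GATS2i), the lowest Burden-matrix eigenvalue (BCUTw-1l), carbon type C3SP2,
  the Galvez topological charge index GGI5, PubChem-style substructure keys
  (bits 38, 257, 503, 738), the C–(O,N,S) bond count SubFPC295, the bond-order
  to path-count ratio R_TpiPCTPC, a fragment-based dipolarity/polarizability
  estimate MLFER_S, the hydrogen E-state maximum maxHother, the detour-matrix
  eigenvector descriptor VE3_Dt and the single-bond count nBondsS3 — each
  validated against independent brute-force oracles in the test suite.
* **Four frozen MLR equations** for Log BMF_L, stored at printed precision:
  a split model and its full-data recalibration on high/medium-quality data
  (`eq1`, `eq2`, 115 and 152 training chemicals), and the corresponding pair
  on the extended dataset that adds screened low-quality data (`eq3`, `eq4`,
  194 and 258 chemicals). For example

  ```
  eq4:  Log BMF_L = −1.04 − 0.42·SubFPC295 + 1.38·PubchemFP503 − 0.06·R_TpiPCTPC
                    + 0.57·MLFER_S + 0.73·GGI5 − 1.05·maxHother − 5.00e−3·VE3_Dt
  ```

* **Model building and validation** — response-ordered train/prediction
  splitting, OLS with full diagnostics, Q²(LOO) via the hat identity,
  Q²(LMO), Q²-F3, Lin's CCC, five-fold cross-validation with per-fold
  genetic-algorithm descriptor re-selection, all-subset search and GA
  variable subset selection (seeded, elitist), recurrent-outlier detection
  and recalibration.
* **Applicability domain** — leverage vs standardized residuals (Williams
  plot) with the h* = 3p′/n cutoff, and the consistency screen that
  classifies externally measured (e.g. low-quality) data as consistent,
  inconsistent, or outside-domain/unreliable.
* **Synthetic fixtures** — a seeded generator of PCB/PAH/benzene/chain
  template libraries with planted linear structure–activity relationships,
  so every stage is testable without measured data.

The estimator classes (`DescriptorCalculator`, `MLRModel`,
`GASubsetSelector`, `LeverageDomain`) follow scikit-learn conventions and
compose with its pipelines; module-level functions mirror them.

## Worked example

```python
from bmfqsar import DescriptorCalculator, builtin_model, classify_biomagnifier

model = builtin_model("eq4")          # recommended full-data model
chems = {"hexachlorobenzene": "Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl",
         "diethyl ether": "CCOCC",
         "2,4'-dichlorobiphenyl": "Clc1ccc(-c2ccccc2Cl)cc1"}
X = DescriptorCalculator(model.descriptor_names).fit_transform(chems.values())
for name, pred in zip(chems, model.predict(X)):
    print(f"{name:24s} LogBMF_L = {pred:6.2f}   biomagnifier: {classify_biomagnifier(pred)}")
```

prints

```
hexachlorobenzene        LogBMF_L =  -0.63   biomagnifier: False
diethyl ether            LogBMF_L =  -1.69   biomagnifier: False
2,4'-dichlorobiphenyl    LogBMF_L =  -0.07   biomagnifier: False
```

i.e. none of the three is predicted to biomagnify through fish diet
(Log BMF_L stays below 0), with the dichlorobiphenyl closest to the
threshold — the chlorinated aromatic fragment key (PubchemFP503 = 1) pushes
its prediction up, while the ether's two C–O bonds (SubFPC295 = 2) pull its
prediction down. Note that MLFER_S here comes from a package-local
(synthetic) fragment table, so absolute predictions are not expected to
match descriptor values from other software bit-for-bit; conventions are
recorded in `bmfqsar.PROVENANCE`.

The same workflow is available from the shell:

```bash
bmfqsar predict data.csv --model eq4 -o predictions.csv
bmfqsar ad data.csv --model eq4 -o williams.csv     # leverage/residual table
bmfqsar screen train.csv lowquality.csv --model eq2
```

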
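# longvbm

Longitudinal voxel-based morphometry for serial 3-D brain images, exercised
end-to-end on synthetic longitudinal phantom cohorts with known ground-truth
atrophy.

The pipeline follows the two-level summary-statistic design for unbalanced
serial data:

1. **Phantoms** (`longvbm.phantoms`) — nested-sphere brain phantoms with
   designated GM regions that atrophy through analytically synthesized
   radial contraction fields (exact truth deformations and Jacobians),
   WM lesions, intensity bias, a mid-study scanner intensity shift, and
   clinical scores (EDSS / MSFC / T2 lesion load) coupled to the regional
   atrophy rate.
2. **Preprocessing** (`longvbm.preprocess`) — lesion filling from the
   normal-WM intensity model, rigid coregistration (Powell over SSD or
   mutual information), polynomial non-uniformity correction, brain
   extraction.
3. **Within-subject** (`longvbm.within_subject`) — unbiased voxel-wise
   median template over all visits, demons-style high-dimensional warping
   (default regularisation 4, 8 iterations), Jacobian-determinant maps,
   Gaussian-mixture tissue segmentation, and pseudo-time-points
   (template GM probability × visit Jacobian).
4. **Group space** (`longvbm.group_space`) — balanced group-average
   template (all controls + an equal-sized random patient subset),
   normalisation *without modulation*, Gaussian smoothing (default FWHM
   8 mm), explicit GM mask.
5. **First level** (`longvbm.summary_stats`) — voxel-wise OLS slope and
   quadratic-term images per subject over all available time-points;
   EDSS-step conversion and clinical slopes.
6. **Inference** (`longvbm.inference`) — second-level GLM with nuisance
   covariates (age, sex, baseline GM, scanner-upgrade proportion),
   threshold-free cluster enhancement (E=0.5, H=2, 26-connectivity),
   max-statistic permutation FWE (sign-flip / relabel / Freedman–Lane;
   default 5000 permutations, exhaustive enumeration when fewer distinct
   permutations exist), and the post-hoc baseline-subtraction test
   (voxel-wise FWE, no TFCE).
7. **Clinical associations** (`longvbm.clinical_assoc`) — ROI atrophy
   rates, Box–Cox transform with shift, Pearson and partial correlations,
   studentized-residual outlier flagging, one-sample progression tests.

## CLI

```sh
# simulate a cohort (NIfTI volumes + manifest/clinical CSVs + truth JSON)
longvbm simulate --n-patients 12 --n-controls 12 --grid 32 --seed 1 --out cohort/

# full analysis (within-subject -> group -> first/second level -> clinical)
longvbm run-all cohort/ --out results/ --n-perm 1000

# or stage by stage
longvbm within-subject cohort/ --out results/
longvbm second-level cohort/ --out results/
```

Configuration can also come from a YAML file (`--config run.yaml`) mirroring
`longvbm.pipeline.RunConfig`; every setting and seed is echoed into
`results/provenance.json`, and a rerun with the same config and seeds is
bit-identical.

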
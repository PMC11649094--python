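"""Full verification study on a synthetic cohort: FAR/FRR, EER, ROC/AUC, Welch.

Runs the complete pipeline on 5 subjects x 5 captures, enumerates all ordered
genuine/impostor pairs, normalizes Euclidean distances to [0, 1] and sweeps
the accept threshold.
"""

import numpy as np

from hypercut import make_dataset, run_pipeline

ds = make_dataset(5, 5, master_seed=0, shape=(96, 96), wavelengths_nm=np.arange(400, 1001, 20))
res = run_pipeline(ds)
r = res.report

print(f"pairs: {r.n_intra} genuine, {r.n_inter} impostor (ordered)")
print(f"mean distance: genuine {r.mean_intra:.2f} vs impostor {r.mean_inter:.2f}")
print(f"Welch's t-test: t = {r.welch_t:.1f}, df = {r.welch_df:.0f}, two-sided P = {r.welch_p:.3g}")
print(f"EER = {100 * r.eer:.2f}% at normalized threshold {r.eer_threshold:.3f}")
print(f"AUC = {100 * r.auc:.2f}%")
print("low EER / high AUC: thresholding the normalized distance separates "
      "genuine from impostor comparisons almost perfectly on this cohort")
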
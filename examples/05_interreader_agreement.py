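"""Inter-reader agreement of first-order features under mask perturbation.

Emulates two readers segmenting the same lesions: the second reader's mask
is a one-voxel binary dilation of the first.  Features are extracted from
both and compared with Lin's concordance correlation coefficient; CCC > 0.85
flags a feature as highly reproducible.
"""

from scipy.ndimage import binary_dilation

from lungdce import build_feature_table, concordance_pairs, fit_voxelwise, generate_cohort
from lungdce.stats import ccc_report
from lungdce.synthetic import CohortConfig
from lungdce.tofts import ModelConfiguration

cohort = generate_cohort(n_patients=10, frac_hyper=0.3, seed=3,
                         config=CohortConfig(shape=(9, 9, 3)))
config = ModelConfiguration("ETM", "georgiou", "PG")

reader1, reader2 = {}, {}
for p in cohort.patients:
    reader1[p.patient_id] = fit_voxelwise(p.series, p.mask, config)
    dilated = binary_dilation(p.mask)
    reader2[p.patient_id] = fit_voxelwise(p.series, dilated, config)

pairs = concordance_pairs(build_feature_table(reader1), build_feature_table(reader2))
report = ccc_report(pairs)
print(report.round(3).to_string())
print(f"\nhighly reproducible features (CCC > 0.85): "
      f"{report.index[report['highly_reproducible']].tolist()}")
# Median features are typically robust to one voxel of segmentation
# disagreement; SD and 90th-percentile features, driven by map tails, lose
# concordance first.
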
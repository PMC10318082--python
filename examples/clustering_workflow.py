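"""Walk through the automated deconvolution stages on one noisy plate:
LOF outlier curation, 1-D clustering, the full ON/OFF check, and
cluster grouping to a binary image.
"""

import numpy as np

from baccam import (
    ChannelParams,
    DeconvolutionConfig,
    count_and_ratio,
    deconvolute,
    named_pattern,
    oracle_threshold,
    simulate_plate,
)
from baccam.barcodes import IndexTable, default_well_codes

truth = named_pattern("SMILEY")
codes = default_well_codes()
sim = simulate_plate(truth, ChannelParams(seed=21), codes,
                     IndexTable.default()[0])
ratios = count_and_ratio(sim.reads, codes)["blue"]

for menu in (dict(method="gmm", k=2), dict(method="gmm", k=3),
             dict(method="kmeans", k=2), dict(method="dbscan", eps=0.2)):
    res = deconvolute(ratios, DeconvolutionConfig(**menu), truth=truth)
    label = f"{menu['method']}({menu.get('k', menu.get('eps'))})"
    print(f"{label:>11}: {res.outliers.n_outliers} outliers curated, "
          f"{res.model.k} clusters with means {np.round(res.model.means, 3)}, "
          f"mode {res.mode.value}, accuracy {res.accuracy:.3f}")

thr, acc = oracle_threshold(ratios, truth)
print(f"\nforeknowledge threshold {thr:.3f} reaches accuracy {acc:.3f} — "
      "the ceiling the unsupervised pipeline is judged against")

try:  # optional: Fig-style scatter of the stages
    from baccam.viz import plot_deconvolution

    res = deconvolute(ratios, DeconvolutionConfig(method="gmm", k=2), truth=truth)
    plot_deconvolution(res, "deconvolution.png")
    print("wrote deconvolution.png")
except ImportError:
    pass
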
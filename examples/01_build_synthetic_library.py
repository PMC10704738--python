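"""Build a synthetic elicitor-response screen and inspect its labelling.

Generates a 9,991-compound library whose log10 luminescence spans the range
of a real BY-2 cell assay (about 1 to 5.7 log units) with ~3.5% of compounds
at or above the modulator threshold of 4.67, then shows the labelling
arithmetic."""

import numpy as np

from rosscreen import SyntheticSpec, generate_library, label_modulators, planted_truth

spec = SyntheticSpec()  # 9,991 compounds x 219 descriptors, 351 modulators
library = generate_library(spec)

labels, n_modulators = label_modulators(library, threshold=4.67)
print(f"compounds:            {len(library)}")
print(f"descriptors:          {library.n_features}")
print(f"log10 ROS range:      {library.log_ros.min():.2f} .. {library.log_ros.max():.2f}")
print(f"modulators (>=4.67):  {n_modulators}  ({n_modulators / len(library):.1%})")

names, truth = planted_truth(spec, library)
print(f"planted informative descriptors: {names}")
resid = library.log_ros - truth(library.X)
print(f"measurement noise sd (log10 units): {np.std(resid):.3f}")
# The modulator fraction and luminescence range mirror the assay the model
# is meant to emulate; the planted descriptors are what feature selection
# and the regressors should rediscover.
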
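"""Recover a planted connectivity gradient from a synthetic phantom.

The phantom's ROI voxels blend smoothly between two network signals along
one spatial axis; after denoising, the connectopic-mapping chain
(fingerprints → eta² similarity → graph → Laplacian eigenmaps) should
return a dominant gradient that tracks the planted mixing weight g.
"""

import numpy as np
import scipy.stats

from gradpain import PhantomSpec, clean, extract_connectopies, make_phantom

spec = PhantomSpec(seed=0)  # 24×12×7 grid, 500-voxel ROI, T=150, noise sd 0.5
volume, roi, brain, g = make_phantom(spec)
clean_volume, clean_brain = clean(volume, brain)
result = extract_connectopies(clean_volume, roi, clean_brain, align_axis=spec.gradient_axis)

dominant = result.connectopies[0]
r = np.corrcoef(dominant.values, g)[0, 1]
rho = scipy.stats.spearmanr(dominant.values, g).statistic
print(f"target components kept: {result.n_components}")
print(f"dominant connectopy eigenvalue: {dominant.eigenvalue:.4f}")
print(f"Pearson r with planted gradient:  {r:.3f}")
print(f"Spearman rho with planted gradient: {rho:.3f}")
# r near 1 means the extracted gradient reproduces the planted spatial
# ordering of connectivity profiles despite the voxel noise.
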
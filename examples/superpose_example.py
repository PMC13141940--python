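"""Rigid-body superposition: recover a known transform and measure RMSD.

Builds an ideal helix, applies a rigid motion plus coordinate noise, then
superposes the copy back onto the original. The printed RMSD reflects only
the injected noise (per-component sigma 0.2 A -> expected ~0.2*sqrt(3)).
"""

import numpy as np

import oligomod as om
from oligomod.superpose import RigidTransform

helix = om.make_helix(om.HelixSpec(n_residues=30))
transform = RigidTransform(
    np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
    np.array([12.0, -3.0, 5.0]),
)
moved = om.perturb(helix, transform, om.NoiseSpec(seed=2, coordinate_sigma=0.2))

result = om.kabsch_fit(moved.coords(), helix.coords())
print(f"paired atoms:          {result.n_pairs}")
print(f"rmsd after fit (A):    {result.rmsd:.3f}")
print(f"rotation angle (deg):  {result.transform.rotation_angle():.1f}")
# rmsd ~ 0.2*sqrt(3) = 0.35 A: the noise floor, since the rigid part is
# removed exactly; the recovered rotation angle is the inverse of the 90
# degree motion applied above.
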
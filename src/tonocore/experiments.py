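"""Canonical phantom experiments used for validation and calibration checks.

These assemble the package's reference study conditions (the printed sparse
sampling design: log-spaced tone ladder, 20 repetitions per condition,
2-trial epochs with matched baselines, two runs) so that calibration numbers
are always computed under the same conditions, whether from the test suite or
from the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .phantom import make_field_layout, make_schedule, simulate_experiment
from .searchlight import (collapse_to_binary, permuted_label_accuracy,
                          preprocess_timeseries, sphere_neighborhoods)


def chance_calibration(seed: int, n_conditions: int = 8, binary: bool = False,
                       sheet_shape=(20, 20), reps: int = 20,
                       n_permutations: int = 20, noise_sd: float = 1.0,
                       f_min: float = 200.0, f_max: float = 8000.0) -> dict:
    """Mean searchlight accuracy under label permutation on a phantom.

    Simulates the sparse-sampling design (``reps`` repetitions of each of
    ``n_conditions`` log-spaced tones, 2-trial epochs, 4 dummy trials, two
    runs), preprocesses, and runs the pairwise-binary majority-vote
    searchlight with labels permuted uniformly at random ``n_permutations``
    times.  With ``binary=True`` the conditions are first collapsed into a
    low-versus-high problem (chance 50% instead of 1/n).

    Returns the permutation summary dict of
    :func:`~tonocore.searchlight.permuted_label_accuracy` plus the chance
    level and the number of searchlight centres.
    """
    rng = np.random.SeedSequence(seed)
    s_sched, s_sim, s_perm = (int(s.generate_state(1)[0] % 2**31)
                              for s in rng.spawn(3))
    schedule = make_schedule(n_conditions, reps, 2, 4, 2, s_sched,
                             f_min=f_min, f_max=f_max)
    layout = make_field_layout(sheet_shape, {"f_lo": f_min, "f_hi": f_max})
    series = simulate_experiment(layout, None, schedule, noise_sd=noise_sd,
                                 seed=s_sim, n_z=1)
    pre = preprocess_timeseries(series)
    nbh = sphere_neighborhoods(series.brain_mask, series.voxel_size_mm, 4.0)
    labels = pre.labels()
    if binary:
        labels = collapse_to_binary(labels, schedule.nominal_frequencies)
        chance = 50.0
    else:
        chance = 100.0 / n_conditions
    out = permuted_label_accuracy(pre, nbh, n_permutations=n_permutations,
                                  labels=labels, seed=s_perm)
    out["chance_pct"] = chance
    out["n_centers"] = nbh.n_centers
    return out
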
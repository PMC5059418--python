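"""Resolving per-site occupancy on a peptide with two modified lysines.

MS1 cannot tell the two mixed label permutations (light/heavy vs heavy/light)
apart - they share precursor m/z. Fragment ions can: b-ions up to b7 contain
only the first lysine, y-ions up to y10 only the second. The simulated twin
carries a high first-site occupancy (92.3%) and a low second-site occupancy
(1.6%), and the b-/y-run split recovers both independently.
"""

import tempfile

from acylswath import (
    SimPeptideSpec, SimScenario, load_window_scheme, quantify_multisite,
    read_run, read_targets, simulate_run,
)

with tempfile.TemporaryDirectory() as tmp:
    scenario = SimScenario(
        peptides=[SimPeptideSpec("FCKAFNAKTDSIE", (3, 8), (0.923, 0.016))],
        noise=0.0, purity=1.0, seed=2,
    )
    bundle = simulate_run(scenario, tmp)
    scheme = load_window_scheme(bundle.scheme_path)
    run = read_run(bundle.mzml_path, scheme)
    target = read_targets(bundle.targets_path)[0]

    first, second = quantify_multisite(run, scheme, target)
    for r, truth in ((first, 0.923), (second, 0.016)):
        series = {f.series for f in r.fragments}
        print(f"site K{r.site_number}: occupancy {r.median_ratio:.4f} "
              f"(truth {truth}) from {sorted(series)}-ion run, "
              f"{len(r.fragments)} differentiating fragments")
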
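#!/usr/bin/env python
"""SOA time-courses: recovering rhythmic attentional alternation.

For each SOA variant (200/100/40 ms spacing), simulates a 15-subject cohort
whose precision alternates antiphasically between the cued and uncued stream
at a frequency inside that variant's resolvable band, plus a fixed-allocation
control cohort.  The pipeline estimates per-SOA half-normal precisions,
z-normalizes, Fourier-transforms the cued/uncued time-courses, and tests the
across-subject phase differences at the peak-PLV bin against 0 and 180 deg.
"""

from pathlib import Path

import pandas as pd

from huetrack import (
    ObserverModel,
    analyze_alternation,
    build_timecourses,
    design_for,
    make_trial_pairs,
    simulate_cohort,
    stage_rng,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240904
#: alternation frequency simulated per variant (inside each resolvable band)
VARIANT_FREQS = {"exp3a": 1.0, "exp3b": 3.75, "exp3c": 4.6875}


def run_variant(name: str, pairs, alternating: bool) -> dict:
    model = ObserverModel(
        sd_high=8.0,
        sd_low=16.0,
        allocation="alternating" if alternating else "fixed",
        alternation_freq=VARIANT_FREQS[name],
        cue_resets_phase=True,
    )
    records = simulate_cohort(
        model, design_for(name), pairs, 15,
        rng=stage_rng(SEED, f"{name}-{'alt' if alternating else 'flat'}"),
    )
    spec = analyze_alternation(build_timecourses(records))
    v180 = spec.v_test_180
    v0 = spec.v_test_0
    return {
        "variant": name,
        "observer": f"alternating {VARIANT_FREQS[name]} Hz" if alternating else "fixed",
        "peak_freq_hz": round(spec.peak_freq, 4),
        "peak_plv": round(float(spec.plv[spec.peak_bin]), 3),
        "v180": round(v180[0], 2),
        "p180": round(v180[2], 4),
        "v0": round(v0[0], 2),
        "p0": round(v0[2], 4),
        "mean_phase_deg": round(v180[3], 1),
    }


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    pairs = make_trial_pairs(150, rng=stage_rng(SEED, "stimuli"))
    rows = []
    for name in ("exp3a", "exp3b", "exp3c"):
        rows.append(run_variant(name, pairs, alternating=True))
        rows.append(run_variant(name, pairs, alternating=False))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "exp3_spectral.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nAlternating cohorts: peak PLV at the simulated frequency with mean "
        "phase near 180 deg (antiphase, p180 < 0.05). Fixed cohorts: no "
        "reliable phase concentration."
    )


if __name__ == "__main__":
    main()
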
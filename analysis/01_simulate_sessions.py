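#!/usr/bin/env python
"""Generate the synthetic study data: two eyes, full acuity sessions.

Creates a low-density and a high-density synthetic eye (center densities
spanning the foveolar range), each with a 5 x 20-trial QUEST acuity session
whose observer threshold is tied to the eye's Nyquist limit, plus
CDC-directed drift traces for every trial.  Writes the session CSV/JSON
bundles under results/sessions/<eye>/.
"""

import json
from pathlib import Path

from foveolar import io as fio
from foveolar import (
    compute_landmarks,
    density_map,
    tessellate,
)
from foveolar.synthetic import (
    DriftParams,
    MosaicParams,
    generate_mosaic,
    generate_session,
    observer_from_nyquist,
)

SEED = 20240901
EYES = {"eye_low": 11000.0, "eye_high": 16000.0}
# session bundles are bulky regenerable intermediates -> scratch/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "sessions"


def main():
    for i, (name, density) in enumerate(EYES.items()):
        out = OUT / name
        out.mkdir(parents=True, exist_ok=True)
        mosaic_params = MosaicParams(center_density=density,
                                     field_arcmin=40.0, seed=SEED + i)
        mosaic, truth = generate_mosaic(mosaic_params)
        dmap = density_map(mosaic, tessellate(mosaic), stride=4)
        landmarks = compute_landmarks(dmap)
        observer = observer_from_nyquist(landmarks.nyquist_arcsec, ratio=0.84)
        bundle = generate_session(mosaic_params, DriftParams(),
                                  observer, seed=SEED + i)
        fio.write_cone_csv(bundle.mosaic, out / "cones.csv")
        fio.write_trace_csv(bundle.traces, out / "traces.csv")
        fio.write_trials_csv(bundle.trials, out / "trials.csv")
        (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
        print(f"{name}: {bundle.mosaic.n_cones} cones at "
              f"{density:.0f} cones/deg^2 center density; Nyquist "
              f"{landmarks.nyquist_arcsec:.1f} arcsec -> observer threshold "
              f"{observer.threshold_arcsec:.1f} arcsec; "
              f"{len(bundle.trials)} trials written to {out}")


if __name__ == "__main__":
    main()
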
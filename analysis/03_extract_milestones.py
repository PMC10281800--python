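#!/usr/bin/env python
"""Extract the six migratory milestones, their uncertainties and the
full/repeat datasets.

Milestones: departure from the breeding grounds, completion of the
southbound Sahara crossing, arrival to and departure from the wintering
grounds, departure from the West African stopover, and arrival at the
breeding grounds.  Uncertainty is the gap to the neighbouring fix (2 days
exactly when West-Africa departure rests on a Sahara fix); milestones with
uncertainty above five days are excluded.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from cuculus.config import RunConfig                      # noqa: E402
from cuculus.milestones import repeat_group_histogram     # noqa: E402
from cuculus.pipeline import run_milestones               # noqa: E402

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = RunConfig.from_yaml(Path(__file__).resolve().parents[1]
                          / "configs" / "demo.yaml")
out = run_milestones(cfg)
full, repeat = out["full"], out["repeat"]
print(f"{len(full)} milestones from {full['cycle_id'].nunique()} migratory "
      f"cycles for {full['bird_id'].nunique()} birds after the uncertainty "
      f"filter")
print("repeat-dataset group sizes (cycles per bird-milestone):")
print(repeat_group_histogram(repeat).to_string())
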
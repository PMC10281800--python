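#!/usr/bin/env python
"""Segment the simulated tracks into transmission cycles and stopovers.

Fixes more than 10 h apart open a new transmission cycle; the best location
per cycle is chained into stopovers when consecutive best locations sit
within 50 km of the running centroid, residencies shorter than one day are
dropped, and stopover ends are pushed through missed transmission cycles
when the bird is next seen elsewhere.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from cuculus.config import RunConfig              # noqa: E402
from cuculus.pipeline import run_segment          # noqa: E402

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = RunConfig.from_yaml(Path(__file__).resolve().parents[1]
                          / "configs" / "demo.yaml")
out = run_segment(cfg)
stops = out["stopovers"]
print(f"{len(out['best'])} transmission cycles -> {len(stops)} stopovers "
      f"({int(stops['gap_extended'].sum())} gap-extended)")
print(f"median stopover length: "
      f"{(stops['end'] - stops['start']).median()}")
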
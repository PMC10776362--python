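#!/usr/bin/env python
"""Generate the default two-stage clean-air scenario bundle.

Writes the full synthetic input bundle (exposure, population, mortality,
exposure-response draws, truth record) to scratch/bundle for the later
analysis steps, and prints a short description of the scenario.
"""

from pathlib import Path

from airburden import ScenarioConfig, make_scenario, write_bundle

OUT = Path("scratch/bundle")

config = ScenarioConfig(seed=1)
bundle = make_scenario(config, n_draws=100)
write_bundle(bundle, OUT)

print(f"scenario: {config.n_rows}x{config.n_cols} cells, years {config.years}")
print(f"  {len(bundle.erf_set)} exposure-response curves, "
      f"{bundle.erf_set[0].n_draws} draws each")
print(f"  total adult population {config.total_population:.3g}, "
      f"LE0 = {config.life_expectancy_at_birth} y")
print(f"bundle written to {OUT}")
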
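"""Consumables for 96 samples: spread plates versus one microplate run."""

import json

from platequant.resources import (
    compare_protocols,
    high_throughput_default,
    spread_plate_default,
)

table = compare_protocols(spread_plate_default(96), high_throughput_default(96))
print(json.dumps(table, indent=2))
print()
print("Three plated dilutions per sample put the classical route at 288")
print("dishes and 5760 mL of agar; the 96-well route uses one plate and")
print("9.6 mL, and the per-sample cost ratio is "
      f"{table['ratios']['cost_per_sample']:.2f}x.")
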
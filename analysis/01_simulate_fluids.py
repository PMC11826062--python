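#!/usr/bin/env python
"""Generate a synthetic per-site fluid-chemistry table.

Emulates the field dataset's composition: one Type I groundwater, a
majority of hyperalkaline Type II fluids, and conservative Si-DIC mixtures
in between. Writes results/synthetic_fluids.tsv in the standard sample
schema (CH4 included, so the affinity and flux stages are fully
exercisable downstream).
"""

from pathlib import Path

import serpenergy as sp

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = sp.SyntheticConfig(seed=20260923)
    samples = sp.generate(config)
    path = OUT / "synthetic_fluids.tsv"
    sp.write_samples(samples, path, dialect="tsv")
    n2 = sum(s.fluid_type is sp.FluidType.TYPE2 for s in samples)
    print(f"wrote {len(samples)} synthetic samples ({n2} Type II) to {path}")


if __name__ == "__main__":
    main()
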
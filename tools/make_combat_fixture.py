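"""One-time generation of the ComBat cross-implementation fixture.

Writes a small subjects-by-features table with known site and group structure
plus the covariate columns to tests/fixtures/, then tools/make_combat_fixture.R
runs the Bioconductor reference implementation (sva::ComBat) on it and freezes
its output next to the input. The test suite reads both files and compares the
package's own harmonization against the frozen reference output; it never needs
R. Re-run both scripts only to regenerate the fixture.
"""

from pathlib import Path

import numpy as np
import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "tests" / "fixtures"


def main() -> None:
    rng = np.random.default_rng(20240917)
    n_per_cell, n_feat = 10, 15
    site = np.repeat(["A", "B"], 2 * n_per_cell)
    group = np.tile(np.repeat(["HC", "PAT"], n_per_cell), 2)
    age = rng.normal(28, 6, size=site.size).round(2)
    x = rng.normal(0, 1, size=(site.size, n_feat))
    x += np.where(group == "PAT", 1.0, 0.0)[:, None]  # preserved group effect
    x += 0.02 * (age - age.mean())[:, None]
    x += np.where(site == "B", 1.5, 0.0)[:, None]  # additive site effect
    x *= np.where(site == "B", 1.4, 1.0)[:, None]  # multiplicative site effect

    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_feat)])
    df.insert(0, "site", site)
    df.insert(1, "group", group)
    df.insert(2, "age", age)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "combat_input.tsv", sep="\t", index=False, float_format="%.10g")
    print(f"wrote {OUT / 'combat_input.tsv'} ({site.size} subjects x {n_feat} features)")


if __name__ == "__main__":
    main()
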
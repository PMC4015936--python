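"""Round-trip ranking data through the two on-disk representations.

Writes a small dataset as an *ordering* table (items listed in placed order)
and as a *ranking* table (position recorded per item), then reads both back.
"""

import tempfile
from pathlib import Path

from crowdrank import ScenarioSpec, generate_dataset, read_dataset, write_dataset

gen = generate_dataset(ScenarioSpec(n_items=4, n_participants=3, seed=8))
d = gen.dataset

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_dataset(d, tmp / "orderings.csv", "ordering", truth_path=tmp / "truth.csv")
    write_dataset(d, tmp / "rankings.tsv", "ranking")

    print("ordering representation (cells are 1-based item indices, placed order):")
    print((tmp / "orderings.csv").read_text())
    print("ranking representation (cells are 1-based positions per item):")
    print((tmp / "rankings.tsv").read_text())

    back1 = read_dataset(tmp / "orderings.csv", "ordering", truth_path=tmp / "truth.csv")
    back2 = read_dataset(tmp / "rankings.tsv", "ranking")
    print("round trips reproduce the dataset:",
          back1.rankings.tolist() == d.rankings.tolist()
          and back2.rankings.tolist() == d.rankings.tolist())
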
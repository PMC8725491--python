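"""Generate the three reference panels and report their shape.

Writes results/panels/{breeds,families,wf}.{dosages.tsv,map,groups}.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _panels import breeds_panel, family_panel, wf_panel


def main() -> None:
    for name, build in (
        ("breeds", breeds_panel),
        ("families", family_panel),
        ("wf", wf_panel),
    ):
        data = build()
        groups = data.samples["group"].value_counts()
        print(
            f"{name}: {data.n_samples} samples x {data.n_markers} markers, "
            f"{len(groups)} group(s) (sizes {groups.min()}–{groups.max()})"
        )
    print("panels written under results/panels/")


if __name__ == "__main__":
    main()
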
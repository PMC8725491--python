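"""Shared reference panels for the numbered analysis drivers.

Three synthetic panels stand in for the restricted genotype data the
analysis layout was designed around:

* ``breeds`` — four Balding–Nichols populations (theta = 0.08) of 150
  samples each, 4,000 markers: the breed-structure panel for diversity,
  F_ST, relatedness and PCA.
* ``families`` — ten paternal half-sib families of 20 progeny on a
  near-panmictic base: the within-group relatedness panel.
* ``wf`` — a Wright–Fisher population of effective size 100 (2
  chromosomes x 500 markers at 50 kb), 200 generations: the LD-decay /
  Ne panel.

Panels regenerate deterministically on demand, so any driver can run on
its own.
"""

from pathlib import Path

import herdstat as h

RESULTS = Path(__file__).resolve().parent.parent / "results"
PANELS = RESULTS / "panels"

SEED = 20260923

BREED_SPEC = h.DivergenceSimSpec(
    n_populations=4, n_per_population=150, n_markers=4000, theta=0.08,
    marker_spacing=55_000, seed=SEED,
)
FAMILY_SPEC = h.FamilySimSpec(
    n_sires=10, progeny_per_sire=20,
    base_spec=h.DivergenceSimSpec(
        n_populations=1, n_per_population=150, n_markers=2000, theta=1e-3,
        seed=SEED + 1,
    ),
    seed=SEED + 1,
)
WF_SPEC = h.WrightFisherSimSpec(seed=SEED + 2)  # N = 100, 2 x 500 @ 50 kb, 200 gen


def breeds_panel() -> h.GenotypeDataset:
    return _cached("breeds", lambda: h.simulate_divergent_populations(BREED_SPEC))


def family_panel() -> h.GenotypeDataset:
    return _cached("families", lambda: h.simulate_families(FAMILY_SPEC))


def wf_panel() -> h.GenotypeDataset:
    return _cached("wf", lambda: h.simulate_wright_fisher(WF_SPEC, 100)[0])


def _cached(name: str, build) -> h.GenotypeDataset:
    prefix = PANELS / name
    if (PANELS / f"{name}.dosages.tsv").exists():
        return h.read_genotypes(prefix, "dosage-matrix")
    data = build()
    PANELS.mkdir(parents=True, exist_ok=True)
    h.write_genotypes(data, prefix, "dosage-matrix")
    return data
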
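import random

import pytest

from pollenrisk.core import CompoundTox, PesticideClass, ResidueRecord, SprayEvent
from pollenrisk.io import default_toxdb


@pytest.fixture(scope="session")
def toxdb():
    """The bundled 25-compound toxicity panel."""
    return default_toxdb()


def make_small_study(rng: random.Random, max_sites: int = 5, max_compounds: int = 5):
    """A tiny random study (residues, toxdb, sprays) for oracle comparisons.

    Includes missing-LD50 compounds, non-detects and unsprayed compounds so
    every code path of the hazard module is exercised.
    """
    from datetime import date

    n_sites = rng.randint(1, max_sites)
    n_comp = rng.randint(1, max_compounds)
    tox = {}
    for i in range(n_comp):
        name = f"C{i}"
        tox[name] = CompoundTox(
            name=name,
            pclass=rng.choice(list(PesticideClass)),
            contact_ld50=None if rng.random() < 0.2 else rng.uniform(0.01, 300),
            oral_ld50=None if rng.random() < 0.2 else rng.uniform(0.01, 300),
        )
    residues, sprays = [], []
    for s in range(n_sites):
        sid = f"S{s}"
        for name in tox:
            lod = rng.uniform(0.5, 30)
            conc = 0.0 if rng.random() < 0.3 else rng.uniform(0, 800)
            residues.append(ResidueRecord.from_measurement(sid, name, conc, lod))
            if rng.random() < 0.5:
                sprays.append(
                    SprayEvent(
                        site_id=sid,
                        compound=name,
                        date=date(2015, 5, rng.randint(7, 22)),
                        pct_ai=rng.uniform(1, 100),
                        app_rate=rng.uniform(0.1, 5),
                        during_bloom=rng.random() < 0.7,
                    )
                )
    return residues, tox, sprays
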
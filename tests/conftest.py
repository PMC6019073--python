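import numpy as np
import pytest

from dnproj.catalog import (
    DNCatalog,
    DNRecord,
    Polarity,
    load_default_atlases,
)

LATERALITIES = ("ipsilateral", "contralateral")
TRACTS = ("DLT", "MDA", "MTD", "ITD", "VLT", "DLV", "VTV")


def make_record(type_id, brain=None, vnc=None, kind="unique", n_pairs=1,
                laterality="ipsilateral", tract="MTD"):
    """Build a record from {neuropil: polarity-value} shorthand dicts."""
    brain = {k: Polarity(v) if isinstance(v, str) else v for k, v in (brain or {}).items()}
    vnc = {k: Polarity(v) if isinstance(v, str) else v for k, v in (vnc or {}).items()}
    return DNRecord(
        type_id=type_id,
        soma_group=type_id[2],
        kind=kind,
        n_pairs=n_pairs,
        laterality=laterality,
        tract=tract,
        brain_innervation=brain,
        vnc_innervation=vnc,
    )


@pytest.fixture(scope="session")
def atlases():
    return load_default_atlases()


@pytest.fixture
def toy_catalog(atlases):
    """Two DNs: one posterior-slope-to-wing, one GNG-to-wing-and-foreleg."""
    brain, vnc = atlases
    recs = [
        make_record("DNp01", brain={"IPS": "smooth"}, vnc={"wing": "varicose"}),
        make_record(
            "DNg01",
            brain={"GNG": "smooth"},
            vnc={"wing": "varicose", "foreleg": "varicose"},
            tract="ITD",
        ),
    ]
    return DNCatalog(recs, brain, vnc)


def random_catalog(seed, n_types=12, p=0.25, with_intensity=False):
    """Unstructured random catalog for oracle-equivalence tests."""
    brain, vnc = load_default_atlases()
    rng = np.random.default_rng(seed)
    values = ("smooth", "varicose", "both")
    recs = []
    counters = {}
    for _ in range(n_types):
        g = str(rng.choice(list("abcdgpx")))
        counters[g] = counters.get(g, 0) + 1
        kind = "population" if rng.random() < 0.3 else "unique"
        brain_ann = {}
        for a in brain.abbreviations:
            if rng.random() < p:
                v = str(rng.choice(values))
                inten = int(rng.integers(1, 3)) if with_intensity and rng.random() < 0.5 else None
                brain_ann[a] = Polarity(v, inten)
        vnc_ann = {}
        for a in vnc.abbreviations:
            if rng.random() < p:
                vnc_ann[a] = Polarity(str(rng.choice(("varicose", "both"))))
        recs.append(
            DNRecord(
                type_id=f"DN{g}{counters[g]:02d}",
                soma_group=g,
                kind=kind,
                n_pairs=int(rng.integers(2, 9)) if kind == "population" else 1,
                laterality=str(rng.choice(LATERALITIES)),
                tract=str(rng.choice(TRACTS)),
                brain_innervation=brain_ann,
                vnc_innervation=vnc_ann,
            )
        )
    return DNCatalog(recs, brain, vnc)


@pytest.fixture
def random_catalog_factory():
    return random_catalog
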
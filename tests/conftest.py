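"""Shared fixtures: a small hand-built invertebrate taxonomy and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from preyassign.taxonomy import Taxon, TaxonomyIndex


@pytest.fixture(scope="session")
def mini_taxonomy() -> TaxonomyIndex:
    """A compact taxonomy of soil invertebrates: harvestmen, spiders,
    flatworms and earthworms, including unranked clades (Laniatores,
    RTA clade, Metazoa/Bilateria above phylum)."""
    rows = [
        # id, name, rank, parent
        ("root", "root", "no rank", None),
        ("metazoa", "Metazoa", "no rank", "root"),
        ("bilateria", "Bilateria", "no rank", "metazoa"),
        ("lophotrochozoa", "Lophotrochozoa", "no rank", "bilateria"),
        # arthropods
        ("arthropoda", "Arthropoda", "phylum", "bilateria"),
        ("arachnida", "Arachnida", "class", "arthropoda"),
        ("opiliones", "Opiliones", "order", "arachnida"),
        ("laniatores", "Laniatores", "no rank", "opiliones"),
        ("gonyleptoidea", "Gonyleptoidea", "superfamily", "laniatores"),
        ("gonyleptidae", "Gonyleptidae", "family", "gonyleptoidea"),
        ("promitobates", "Promitobates", "genus", "gonyleptidae"),
        ("p_ornatus", "Promitobates ornatus", "species", "promitobates"),
        ("p_bellus", "Promitobates bellus", "species", "promitobates"),
        ("pachyloides", "Pachyloides", "genus", "gonyleptidae"),
        ("p_thorellii", "Pachyloides thorellii", "species", "pachyloides"),
        ("stygnidae", "Stygnidae", "family", "gonyleptoidea"),
        ("pickeliana", "Pickeliana", "genus", "stygnidae"),
        ("p_pickeli", "Pickeliana pickeli", "species", "pickeliana"),
        ("araneae", "Araneae", "order", "arachnida"),
        ("rta_clade", "RTA clade", "no rank", "araneae"),
        ("sparassidae", "Sparassidae", "family", "rta_clade"),
        ("eusparassus", "Eusparassus", "genus", "sparassidae"),
        ("e_walckenaeri", "Eusparassus walckenaeri", "species", "eusparassus"),
        ("caayguara", "Caayguara", "genus", "sparassidae"),
        ("c_albus", "Caayguara albus", "species", "caayguara"),
        ("araneidae", "Araneidae", "family", "araneae"),
        ("phonognatha", "Phonognatha", "genus", "araneidae"),
        ("p_graeffei", "Phonognatha graeffei", "species", "phonognatha"),
        ("insecta", "Insecta", "class", "arthropoda"),
        ("hymenoptera", "Hymenoptera", "order", "insecta"),
        ("lepidoptera", "Lepidoptera", "order", "insecta"),
        ("bombycidae", "Bombycidae", "family", "lepidoptera"),
        ("bombyx", "Bombyx", "genus", "bombycidae"),
        ("b_mori", "Bombyx mori", "species", "bombyx"),
        # flatworms
        ("platyhelminthes", "Platyhelminthes", "phylum", "lophotrochozoa"),
        ("rhabditophora", "Rhabditophora", "class", "platyhelminthes"),
        ("tricladida", "Tricladida", "order", "rhabditophora"),
        ("geoplanoidea", "Geoplanoidea", "superfamily", "tricladida"),
        ("geoplanidae", "Geoplanidae", "family", "geoplanoidea"),
        ("imbira", "Imbira", "genus", "geoplanidae"),
        ("i_marcusi", "Imbira marcusi", "species", "imbira"),
        ("cephaloflexa", "Cephaloflexa", "genus", "geoplanidae"),
        ("c_bergi", "Cephaloflexa bergi", "species", "cephaloflexa"),
        ("obama", "Obama", "genus", "geoplanidae"),
        ("obama_sp", "Obama sp.", "species", "obama"),
        # annelids
        ("annelida", "Annelida", "phylum", "lophotrochozoa"),
        ("clitellata", "Clitellata", "class", "annelida"),
        ("haplotaxida", "Haplotaxida", "order", "clitellata"),
        ("lumbricoidea", "Lumbricoidea", "superfamily", "haplotaxida"),
        ("lumbricidae", "Lumbricidae", "family", "lumbricoidea"),
        ("rhinodrilidae", "Rhinodrilidae", "family", "lumbricoidea"),
        ("pontoscolex", "Pontoscolex", "genus", "rhinodrilidae"),
        ("p_corethrurus", "Pontoscolex corethrurus", "species", "pontoscolex"),
        ("p_spiralis", "Pontoscolex spiralis", "species", "pontoscolex"),
    ]
    return TaxonomyIndex(Taxon(i, n, r, p) for i, n, r, p in rows)


def random_taxonomy(rng: np.random.Generator) -> TaxonomyIndex:
    """A random balanced ranked taxonomy (fan-outs 1-3 per level)."""
    from preyassign.synthetic import generate_taxonomy

    shape = tuple(int(rng.integers(1, 4)) for _ in range(7))
    return generate_taxonomy(shape)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
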
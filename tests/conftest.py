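import numpy as np
import pandas as pd
import pytest

from sulfurcycle.capabilities import GeneHit, GenomeRecord
from sulfurcycle.fluxes import TimeCoursePanel


def make_panel(series, sediment_g=1.0, liquid_L=0.099, lod=None, incubation_id="test"):
    """Build a panel from {(species, group): {replicate: [conc, ...]}} plus
    a shared time grid inferred from series length (10-min steps)."""
    rows = []
    for (species, group), reps in series.items():
        for rep, concs in reps.items():
            for i, c in enumerate(concs):
                rows.append(
                    {
                        "species": species,
                        "group": group,
                        "replicate": rep,
                        "time_h": i / 6.0,
                        "conc_uM": c,
                    }
                )
    return TimeCoursePanel(
        incubation_id=incubation_id,
        data=pd.DataFrame(rows),
        sediment_g=sediment_g,
        liquid_L=liquid_L,
        lod_uM=lod or {},
    )


@pytest.fixture
def sulfide_panel():
    """Three-replicate declining sulfide series with a flat blank."""
    return make_panel(
        {
            ("sulfide", "experimental"): {
                1: [1000.0, 800.0, 680.0, 620.0],
                2: [1010.0, 812.0, 690.0, 628.0],
                3: [990.0, 788.0, 670.0, 612.0],
            },
            ("sulfide", "control"): {
                1: [1000.0, 890.0, 830.0, 800.0],
                2: [1000.0, 888.0, 828.0, 798.0],
                3: [1000.0, 892.0, 832.0, 802.0],
            },
            ("sulfide", "blank"): {
                1: [1000.0, 1000.0, 1000.0, 1000.0],
                2: [1000.0, 1000.0, 1000.0, 1000.0],
                3: [1000.0, 1000.0, 1000.0, 1000.0],
            },
        }
    )


def genome_with(families, genome_id="G1", completeness=95.0, contamination=1.0,
                taxonomy="d__Bacteria;p__Proteobacteria"):
    """Genome record with one hit per family, laid out along one scaffold."""
    hits = [
        GeneHit(genome_id=genome_id, scaffold_id=f"{genome_id}_sc0", family=f,
                start=1000 * (i + 1), end=1000 * (i + 1) + 900, strand="+")
        for i, f in enumerate(families)
    ]
    return GenomeRecord(
        genome_id=genome_id, taxonomy=taxonomy,
        completeness=completeness, contamination=contamination, hits=hits,
    )


def shdr_scaffold(subtypes, scaffold_id="sc_shdr", genome_id="G1", other_between=()):
    """Hits for one scaffold: sHdr subunits in the given coordinate order,
    optionally with non-sHdr genes interleaved at the given indices."""
    hits = []
    pos = 100
    for i, sub in enumerate(subtypes):
        if i in other_between:
            hits.append(GeneHit(genome_id, scaffold_id, "sqr", None, pos, pos + 800, "+"))
            pos += 1000
        hits.append(GeneHit(genome_id, scaffold_id, "shdr_subunit", sub, pos, pos + 800, "+"))
        pos += 1000
    return hits
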
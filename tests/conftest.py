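import numpy as np
import pytest

from asdscan import (
    CoverageTrack,
    Gene,
    SimConfig,
    load_nn_params,
    simulate_libraries,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def nn_params():
    return load_nn_params("default")


@pytest.fixture(scope="session")
def toy_genome():
    """One plus-strand gene with an AUG start and three internal AUGs, plus a
    minus-strand gene; generous flanks so scoring windows never truncate."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))

    def random_seq(n):
        # avoid accidental ATG so the internal-AUG census is by construction
        while True:
            s = "".join(rng.choice(bases, size=n))
            if "ATG" not in s and "CAT" not in s:
                return s

    # CDS for gene 1: ATG + filler with ATG planted at codon offsets 30,60,90
    filler = list(random_seq(150 - 6))
    cds1 = list("ATG" + "".join(filler) + "TAA")
    for off in (30, 60, 90):
        cds1[off : off + 3] = "ATG"
    cds1 = "".join(cds1)
    left = random_seq(120)
    mid = random_seq(120)
    right = random_seq(120)
    cds2 = "ATG" + random_seq(60 - 6) + "TAA"
    # gene 2 on the minus strand: insert the reverse complement
    comp = str.maketrans("ACGT", "TGCA")
    genome = {"toy": left + cds1 + mid + cds2.translate(comp)[::-1] + right}
    g1 = Gene("gene1", "toy", "+", 120, 120 + len(cds1))
    g2_start = 120 + len(cds1) + 120
    g2 = Gene("gene2", "toy", "-", g2_start, g2_start + len(cds2))
    return genome, [g1, g2]


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by several integration tests."""
    cfg = SimConfig(n_genes=60, variants=("C", "A"), seed=11)
    tx = simulate_transcriptome(cfg)
    libs = {
        (v, ret): simulate_libraries(cfg, tx, v, retapamulin=ret)
        for v in ("C", "A")
        for ret in (False, True)
    }
    return cfg, tx, libs


def make_track(lengths, **arrays):
    """Build a raw CoverageTrack from keyword arrays keyed 'replicon_strand'."""
    track = CoverageTrack.zeros(lengths)
    total = 0.0
    for key, arr in arrays.items():
        replicon, strand = key.rsplit("_", 1)
        strand = {"plus": "+", "minus": "-"}[strand]
        vec = track.get(replicon, strand)
        arr = np.asarray(arr, dtype=float)
        vec[: len(arr)] = arr
        total += arr.sum()
    track.total_mapped = total
    return track
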
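import numpy as np
import pytest

from metaclone.simulate import patient1_config, simulate_cohort


@pytest.fixture(scope="session")
def patient1_cohort():
    """Noiseless 3-lesion cohort with the 63/2/2/8/37 structure and the
    third lesion under the A:T>G:C process."""
    return simulate_cohort(patient1_config(error_rate=0.0), seed=11)


@pytest.fixture(scope="session")
def toy_reference():
    """Tiny two-contig reference for hand-built spectrum/context cases."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        "chr1": bases[rng.integers(0, 4, size=4000)].tobytes().decode(),
        "chr2": bases[rng.integers(0, 4, size=4000)].tobytes().decode(),
    }


def make_variant(
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    lesion="M1",
    patient="P1",
    vaf=0.5,
    depth=100,
    gene="",
    effect="other",
):
    from metaclone.io_formats import GenomicVariant

    return GenomicVariant(
        patient_id=patient,
        lesion_id=lesion,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        depth=depth,
        alt_reads=int(round(vaf * depth)),
        gene=gene,
        effect=effect,
    )
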
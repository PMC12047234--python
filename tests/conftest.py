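import numpy as np
import pytest

from rcakit import synth


@pytest.fixture(scope="session")
def small_panel() -> synth.VariantPanel:
    """100-site panel, VAF ~ N(0.3, 0.15) truncated, purity 1."""
    return synth.generate_variant_panel(100, vaf_mean=0.3, vaf_sd=0.15, purity=1.0, seed=0)


@pytest.fixture(scope="session")
def uniform_panel() -> synth.VariantPanel:
    """Panel where every site has the same MUT probability 0.5."""
    return synth.generate_variant_panel(20, vaf_mean=0.5, vaf_sd=0.0, purity=1.0, seed=1)


def make_consensus_read(chrom="1", start=1000, end=1167, n_repeats=5, timestamp=0.0, seq="A" * 10):
    from rcakit.consensus import ConsensusRead

    return ConsensusRead(
        template_id=f"{chrom}:{start}-{end}",
        seq=seq,
        qual=tuple([30] * len(seq)),
        n_repeats=n_repeats,
        coords=(chrom, start, end),
        timestamp=timestamp,
    )
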
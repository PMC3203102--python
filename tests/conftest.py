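import math

import numpy as np
import pandas as pd
import pytest

from lclfidelity.config import BASES, SimulationConfig
from lclfidelity.genotyper import SitePileup
from lclfidelity.simulate import PILEUP_COLUMNS


def make_pileup(ref="A", alt="C", ref_fwd=10, ref_rev=10, alt_fwd=0, alt_rev=0,
                alt_bq=40.0, mq=40.0, chrom="chr1", pos=100, **extra_counts):
    """Build a scalar SitePileup with the given ref/alt strand counts."""
    counts = {ref: (ref_fwd, ref_rev), alt: (alt_fwd, alt_rev)}
    counts.update(extra_counts)
    bq = {b: alt_bq for b in counts}
    return SitePileup(chrom=chrom, pos=pos, ref=ref, counts=counts,
                      base_quality=bq, mapping_quality=mq)


def make_pileup_frame(rows, sample="s1", source="PBMC", chrom="chr1"):
    """Build a pileup table from (pos, ref, {base: (fwd, rev)}, bq, mq) tuples."""
    recs = []
    for pos, ref, counts, bq, mq in rows:
        rec = {"chrom": chrom, "pos": pos, "sample": sample, "source": source,
               "ref": ref, "mq": mq}
        for b in BASES:
            f, r = counts.get(b, (0, 0))
            rec[f"{b}_fwd"], rec[f"{b}_rev"] = f, r
            rec[f"{b}_bq"] = bq if (f + r) else 0.0
        recs.append(rec)
    return pd.DataFrame(recs, columns=list(PILEUP_COLUMNS))


def oracle_genotype_posterior(n_ref, n_alt, het_prior, error_rate):
    """Independent log-space enumeration of the 3-genotype posterior."""
    n, k = n_ref + n_alt, n_alt
    logc = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    def loglik(p):
        if p == 0.0:
            return logc if k == 0 else -math.inf
        if p == 1.0:
            return logc if k == n else -math.inf
        return logc + k * math.log(p) + (n - k) * math.log(1.0 - p)

    theta = het_prior
    priors = [1 - theta - theta ** 2, theta, theta ** 2]
    z = sum(priors)
    logs = [loglik(p) + math.log(pr / z)
            for p, pr in zip((error_rate, 0.5, 1 - error_rate), priors)]
    m = max(logs)
    ws = [math.exp(x - m) for x in logs]
    total = sum(ws)
    return [w / total for w in ws]


@pytest.fixture
def small_config():
    """A fast, fully-featured simulation: ~200 calls/sample at 125X."""
    return SimulationConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
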
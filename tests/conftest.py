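import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rbomics.simulate import CohortSimConfig, simulate_variant_cohort


def make_variant(**overrides) -> dict:
    """A well-supported somatic SNV that passes every filter by default."""
    base = dict(
        sample_id="T001", chrom="chr1", pos=1000, ref="A", alt="T",
        variant_type="SNV", functional_class="nonsynonymous_exonic",
        tumor_alt_reads=30, tumor_ref_reads=70, blood_alt_reads=0.0,
        tumor_vaf=0.30, pop_maf_1000g=float("nan"), pop_maf_esp=float("nan"),
        in_dbsnp=False, dbsnp_pop_maf=float("nan"),
        dbsnp_single_mapping=False, dbsnp_clinical_tag=False,
        matched_normal_available=True,
    )
    base.update(overrides)
    return base


def cohort_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([make_variant(**r) if isinstance(r, dict) else r
                         for r in rows])


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortSimConfig(n_tumors=15, somatic_rate=8, germline_rate=12,
                          artifact_rate=5, frac_matched=0.8, seed=42)
    return simulate_variant_cohort(cfg)
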
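import numpy as np
import pytest

from genescore.refpanel import import_vcf
from genescore.simulate import (
    LdBlockDesign,
    block_annotation,
    simulate_null_gwas,
    write_panel_vcf,
)


@pytest.fixture(scope="session")
def small_design():
    return LdBlockDesign(n_samples=400, blocks=((3, 0.6),) * 10, seed=1)


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory, small_design):
    """A 10-block, 30-SNP panel imported into the indexed store."""
    d = tmp_path_factory.mktemp("panel")
    write_panel_vcf(small_design, str(d / "panel.vcf"))
    return import_vcf(str(d / "panel.vcf"), str(d / "panel"))


@pytest.fixture(scope="session")
def small_genes(small_design):
    return block_annotation(small_design)


@pytest.fixture(scope="session")
def null_gwas_pair(small_panel):
    g1, g2 = simulate_null_gwas(small_panel, seed=7, n_gwas=2)
    return g1, g2


@pytest.fixture(scope="session")
def calib_design():
    """Larger panel for calibration checks: 200 independent 3-SNP LD blocks."""
    return LdBlockDesign(n_samples=300, blocks=((3, 0.5),) * 200, seed=11)


@pytest.fixture(scope="session")
def calib_panel(tmp_path_factory, calib_design):
    d = tmp_path_factory.mktemp("calib")
    write_panel_vcf(calib_design, str(d / "panel.vcf"))
    return import_vcf(str(d / "panel.vcf"), str(d / "panel"))


@pytest.fixture(scope="session")
def calib_genes(calib_design):
    return block_annotation(calib_design)
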
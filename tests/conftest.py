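import pytest

from phaseplan.chem_core import Mixture
from phaseplan.design import CornerSpec, GridDesign, SeedMode, StockSet


@pytest.fixture
def xylanase_stocks() -> StockSet:
    """Xylanase at 36 mg/ml against an 8.0 M sodium formate cocktail."""
    return StockSet(
        protein_stock=Mixture.of(xylanase=(36, "mg_per_ml")),
        protein_name="xylanase",
        cocktail_stock=Mixture.of(sodium_formate=(8000, "mM")),
        primary_precipitant="sodium_formate",
    )


@pytest.fixture
def citrate_cocktail() -> Mixture:
    """1 M sodium citrate / 167 mM HEPES pH 7.0 cocktail."""
    return Mixture.of(sodium_citrate=(1000, "mM"), HEPES=(167, "mM"), pH=7.0)


def make_stocks(protein_conc=30.0, precipitant_conc=4000.0,
                protein_name="protein", precipitant="salt") -> StockSet:
    return StockSet(
        protein_stock=Mixture.of(**{protein_name: (protein_conc, "mg_per_ml")}),
        protein_name=protein_name,
        cocktail_stock=Mixture.of(**{precipitant: (precipitant_conc, "mM")}),
        primary_precipitant=precipitant,
    )


def make_grid(rows=4, cols=6, drop=2.0, c00=(20, 500), c0n=(20, 2000),
              cn0=(5, 1000), cnn=(5, 3000), seed_mode=SeedMode.NONE,
              seed_fraction=0.1) -> GridDesign:
    return GridDesign(rows=rows, cols=cols, drop_volume=drop,
                      corners=CornerSpec(c00, c0n, cn0, cnn),
                      seed_mode=seed_mode, seed_fraction=seed_fraction)
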
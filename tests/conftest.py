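import random

import pytest

from phoscompare.fixtures import FixturePlan, generate
from phoscompare.io_formats import Modification, ProteinDB, SearchHit
from phoscompare.model import Engine, ModType, Sample
from phoscompare.pipeline import InputFile, RunConfig


@pytest.fixture
def tiny_db():
    """Three short proteins; P12345 holds the canonical SAPSTR example peptide."""
    return ProteinDB(
        records={
            "P12345": ("MKSAPSTR", "sp|P12345|TEST_HUMAN test protein"),
            "P23456": ("MAAAASTKLLRPQSVWK", "sp|P23456|SECOND_HUMAN second protein"),
            "P34567": ("SAPSTRGGSAPSTR", "sp|P34567|REPEAT_HUMAN repeated region"),
        },
        dialect="uniprot",
    )


def make_hit(
    peptide="SAPSTR",
    mods=((1, "S", ModType.PHOSPHO),),
    engine=Engine.MASCOT,
    sample=Sample.CASE,
    accessions=("P12345",),
    scores=None,
    ratio=None,
    file_id="test",
):
    if scores is None:
        scores = {"expect": 0.001, "ion_score": 60.0} if engine == Engine.MASCOT else {"confidence": 99.5}
    return SearchHit(
        engine=engine,
        sample_label=sample,
        file_id=file_id,
        peptide_sequence=peptide,
        protein_accessions=tuple(accessions),
        modifications=tuple(Modification(p, r, m) for p, r, m in mods),
        scores=scores,
        ratio=ratio,
    )


@pytest.fixture
def hit_factory():
    return make_hit


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Medium qualitative fixture bundle shared across tests (read-only)."""
    plan = FixturePlan(
        n_unique_case=15,
        n_unique_control=15,
        n_common=30,
        multi_match_fraction=0.1,
        acetyl_fraction=0.15,
        peptides_per_event_range=(1, 3),
        seed=42,
    )
    return generate(plan, tmp_path_factory.mktemp("bundle"))


def config_for(bundle, out_dir=None, quant=False):
    return RunConfig(
        inputs=[InputFile(p, e, s) for p, e, s in bundle.tables],
        fasta_path=bundle.fasta_path,
        known_site_paths=[bundle.known_sites_path],
        quant=quant,
        out_dir=out_dir,
    )


@pytest.fixture
def bundle_config(bundle):
    return config_for(bundle)


def random_hits(rng: random.Random, n: int, engine: Engine) -> list[SearchHit]:
    """Random but internally consistent SearchHits for parser round-trips."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    hits = []
    for i in range(n):
        length = rng.randint(6, 25)
        peptide = "".join(rng.choice(alphabet) for _ in range(length))
        n_mods = rng.randint(0, 3)
        positions = rng.sample(range(1, length + 1), k=min(n_mods, length))
        mods = []
        for pos in sorted(positions):
            mod_type = rng.choice([ModType.PHOSPHO, ModType.ACETYL])
            mods.append(Modification(pos, peptide[pos - 1], mod_type))
        if engine == Engine.MASCOT:
            scores = {"expect": round(10 ** rng.uniform(-6, -1), 8), "ion_score": round(rng.uniform(10, 100), 2)}
        elif engine == Engine.PARAGON:
            scores = {"confidence": round(rng.uniform(50, 100), 3)}
        else:
            scores = {"xcorr": round(rng.uniform(1, 6), 3)}
        if rng.random() < 0.5:
            scores["localization"] = round(rng.uniform(0, 100), 2)
        hits.append(
            SearchHit(
                engine=engine,
                sample_label=rng.choice([Sample.CASE, Sample.CONTROL]),
                file_id="roundtrip",
                peptide_sequence=peptide,
                protein_accessions=tuple(f"P{rng.randint(10000, 99999)}" for _ in range(rng.randint(1, 3))),
                modifications=tuple(mods),
                scores=scores,
                ratio=round(rng.uniform(0.1, 5.0), 4) if rng.random() < 0.3 else None,
            )
        )
    return hits
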
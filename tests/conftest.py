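import numpy as np
import pytest

from massnovo.decoder import Beam, _legal_token_mask, _mass_termination
from massnovo.model import ModelConfig, SpectrumTransformer, collate
from massnovo.nn import log_softmax_data
from massnovo.spectra_io import preprocess_spectrum
from massnovo.synthetic import SimulationConfig, generate_corpus, noiseless
from massnovo.vocabulary import STOP_INDEX, from_token_ids


def greedy_decode(spectrum, model, filt):
    """Independent token-by-token argmax oracle with the same legality and
    termination rules as the beam search; used to cross-check k=1 decoding."""
    batch = collate([spectrum], with_targets=False)
    memory, mask = model.encode(batch)
    prefix, probs, logps = [], [], []
    max_tokens = model.config.max_length + 1
    for _ in range(max_tokens):
        scores = model.decode_step(
            prefix, memory, mask, spectrum.precursor.mass, spectrum.precursor.charge
        )
        logp = log_softmax_data(scores + _legal_token_mask(Beam(prefix=prefix)))
        tok = int(np.argmax(logp))
        logps.append(float(logp[tok]))
        if tok == STOP_INDEX:
            break
        prefix.append(tok)
        probs.append(float(np.exp(logp[tok])))
        if _mass_termination(
            Beam(prefix=prefix).residue_mass, spectrum.precursor.mass, filt
        ) is not None:
            break
        if len(prefix) >= max_tokens:
            break
    return from_token_ids(prefix[::-1]), float(sum(logps))


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return ModelConfig(n_layers=2, d=64, n_heads=4, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg) -> SpectrumTransformer:
    """Deterministically initialized (untrained) small model."""
    return SpectrumTransformer(tiny_cfg)


@pytest.fixture(scope="session")
def noiseless_corpus():
    """64 noiseless synthetic spectra of short peptides, preprocessed."""
    sim = noiseless(SimulationConfig(n_spectra=64, min_length=6, max_length=10, seed=11))
    return [preprocess_spectrum(s) for s in generate_corpus(sim)]


@pytest.fixture(scope="session")
def noisy_corpus():
    """Spectra with jitter, noise peaks, and fragment dropout (defaults)."""
    sim = SimulationConfig(n_spectra=32, min_length=6, max_length=12, seed=5)
    return [preprocess_spectrum(s) for s in generate_corpus(sim)]
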
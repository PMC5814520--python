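import numpy as np
import pytest

from xlinkquant.chem import MODIFICATIONS
from xlinkquant.linearize import CrossLinkPSM
from xlinkquant.simulate import SimulationParams, build_truth, render_runs


@pytest.fixture(scope="session")
def tiny_world():
    """Small 3-replica injection-like world for fast integration tests."""
    params = SimulationParams(n_pairs=8, n_runs=3, experiment="injection",
                              n_violating=2)
    truth = build_truth(params, seed=7)
    return render_runs(truth)


@pytest.fixture(scope="session")
def noiseless_world():
    """Noise-free world: CV 0, no RT jitter, no run shifts, no noise floor —
    recovered areas must match truth almost exactly."""
    params = SimulationParams(
        n_pairs=10, n_runs=3, experiment="injection", cv_target=0.0,
        rt_jitter_sd=0.0, run_shift_max=0.0, noise_peaks_per_spectrum=0,
        n_absent=0, id_prob=1.0)
    truth = build_truth(params, seed=11)
    return render_runs(truth)


def random_tryptic_peptide(rng: np.random.Generator, min_len=6,
                           max_len=14) -> str:
    alphabet = list("ACDEFGHILMNPQSTVWY")
    n = int(rng.integers(min_len - 1, max_len))
    body = "".join(rng.choice(alphabet, size=n))
    return body + ("K" if rng.random() < 0.5 else "R")


def random_psm(rng: np.random.Generator) -> CrossLinkPSM:
    """A random cross-link PSM with random tryptic peptides and mods."""
    def pep_with_site(seq0: str):
        # force a linkable residue somewhere before the C-terminus
        pos = int(rng.integers(1, len(seq0)))
        seq = seq0[:pos - 1] + rng.choice(list("KSTY")) + seq0[pos:]
        return seq, pos

    pep_a, site_a = pep_with_site(random_tryptic_peptide(rng))
    pep_b, site_b = pep_with_site(random_tryptic_peptide(rng))

    def mods_for(pep: str):
        mods = []
        for i, ch in enumerate(pep, start=1):
            if ch == "C":
                mods.append((i, MODIFICATIONS["cm"]))
            elif ch == "M" and rng.random() < 0.5:
                mods.append((i, MODIFICATIONS["ox"]))
        return tuple(mods)

    return CrossLinkPSM(
        run_id="r1", scan=int(rng.integers(1, 1000)),
        charge=int(rng.integers(3, 8)),
        pep_a=pep_a, pep_b=pep_b, site_a=site_a, site_b=site_b,
        prot_pos_a=int(rng.integers(1, 500)),
        prot_pos_b=int(rng.integers(1, 500)),
        mods_a=mods_for(pep_a), mods_b=mods_for(pep_b),
        score=float(rng.uniform(0, 30)))
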
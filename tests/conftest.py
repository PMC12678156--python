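"""Shared fixtures: small deterministic datasets for every pipeline stage."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

import drugrev as dr


@pytest.fixture(scope="session")
def small_gwas_layer():
    """A 600-variant / 200-gene layer with 5% causal genes."""
    return dr.simulate_gwas_layer(
        n_variants=600, n_genes=200, n_tissues=6, causal_fraction=0.05,
        ld_block_size=3, ld_rho=0.3, seed=101,
    )


@pytest.fixture(scope="session")
def null_gwas_layer():
    """All-null GWAS layer (no causal genes), one variant per gene."""
    return dr.simulate_gwas_layer(
        n_variants=800, n_genes=800, n_tissues=3, causal_fraction=0.0,
        ld_block_size=4, ld_rho=0.3, seed=202,
    )


@pytest.fixture(scope="session")
def disease_signature(small_gwas_layer) -> dr.TissueSignature:
    gwas, ld, weight_sets, annotation, truth = small_gwas_layer
    return dr.impute_signature(truth.causal_tissue,
                               weight_sets[truth.causal_tissue], gwas, ld)


def _enroll(pid, start, end, birth_year=1980, sex="F"):
    return (pid, start, end, birth_year, sex)


@pytest.fixture()
def ten_patient_claims() -> dr.ClaimsTables:
    """Hand-built 10-patient claims with planted eligibility violations.

    Patients p01..p06 are fully eligible; p07 has only 100 days of
    pre-index enrollment (rule 3); p08, p09, p10 carry a myocardial-
    infarction (I21) diagnosis before their index date (rule 4).
    """
    idx = date(2020, 1, 1)
    pre_ok = date(2019, 1, 1)
    end = date(2022, 1, 1)
    enr, dx, rx = [], [], []
    for i in range(1, 11):
        pid = f"p{i:02d}"
        start = date(2019, 9, 23) if i == 7 else pre_ok  # p07: 100 d pre-index
        enr.append(_enroll(pid, start, end))
        dx.append((pid, idx, "G430"))
        rx.append((pid, idx, "triptan", "acute_migraine"))
        if i >= 8:
            dx.append((pid, date(2019, 6, 1), "I219"))
    return dr.ClaimsTables(
        enrollment=pd.DataFrame(
            enr, columns=["person_id", "start_date", "end_date", "birth_year", "sex"]),
        diagnoses=pd.DataFrame(dx, columns=["person_id", "date", "icd10_code"]),
        prescriptions=pd.DataFrame(
            rx, columns=["person_id", "date", "drug_code", "drug_class"]),
    )


@pytest.fixture(scope="session")
def simulated_claims():
    """Moderate simulated claims with one planted protective drug."""
    truth = dr.ClaimsTruth(
        beta0=float(np.log(5.0)), alphas={"drugx": float(np.log(0.81))},
        betas={"betablocker": -0.1}, tau=0.5, sigma=0.6,
    )
    tables, _ = dr.simulate_claims(
        600, truth, n_windows_mean=3.0, seed=303,
        eligibility_noise=dr.EligibilityNoise(0.05, 0.05, 0.02),
    )
    return tables, truth
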
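import numpy as np
import pytest

import dnatorsion as dt


@pytest.fixture(scope="session")
def table():
    return dt.ParamTable.default()


@pytest.fixture(scope="session")
def undamped_table():
    return dt.ParamTable.default().with_beta_scale(0.0)


@pytest.fixture
def fasta_file(tmp_path):
    def write(content: str, name: str = "seq.fasta"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return write


def hand_rhs(seq, phi1, phi2, v1, v2, t=0.0, F0=0.0, omega=0.0, variant="as_printed",
             beta_scale=1.0):
    """Independent scalar evaluation of the equations of motion.

    Written directly from the closed-form torque expressions with python
    floats and math functions — no shared code with the package's
    vectorized or compiled paths.
    """
    import math

    I = {"A": 7.61e-44, "T": 4.86e-44, "G": 8.22e-44, "C": 4.11e-44}
    R = {"A": 5.80e-10, "T": 4.80e-10, "G": 5.70e-10, "C": 4.70e-10}
    K = {"A": 2.35e-18, "T": 1.61e-18, "G": 2.27e-18, "C": 1.54e-18}
    B = {"A": 4.25e-34, "T": 2.91e-34, "G": 4.10e-34, "C": 2.79e-34}
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n = len(seq)
    a1, a2 = [], []
    drive = F0 * math.cos(omega * t)
    for i, b in enumerate(seq):
        c = comp[b]
        k12 = 6.20e-2 if b in "AT" else 9.60e-2
        r1, r2 = R[b], R[c]
        if n == 1:
            tor1 = tor2 = 0.0
        elif i == 0:
            tor1 = K[b] * (phi1[1] - phi1[0])
            tor2 = K[c] * (phi2[1] - phi2[0])
        elif i == n - 1:
            tor1 = K[b] * (phi1[i - 1] - phi1[i])
            tor2 = K[c] * (phi2[i - 1] - phi2[i])
        else:
            tor1 = K[b] * (phi1[i - 1] - 2 * phi1[i] + phi1[i + 1])
            tor2 = K[c] * (phi2[i - 1] - 2 * phi2[i] + phi2[i + 1])
        pair1 = -k12 * r1 * (r1 + r2) * math.sin(phi1[i]) - k12 * r1 * r2 * math.sin(
            phi1[i] - phi2[i]
        )
        if variant == "as_printed":
            pair2 = k12 * r1 * (r1 + r2) * math.sin(phi2[i]) - k12 * r1 * r2 * math.sin(
                phi1[i] - phi2[i]
            )
        else:
            pair2 = -k12 * r2 * (r1 + r2) * math.sin(phi2[i]) + k12 * r1 * r2 * math.sin(
                phi1[i] - phi2[i]
            )
        a1.append((tor1 + pair1 - beta_scale * B[b] * v1[i] + drive) / I[b])
        a2.append((tor2 + pair2 - beta_scale * B[c] * v2[i] + drive) / I[c])
    return np.array(a1), np.array(a2)


@pytest.fixture(scope="session")
def scalar_rhs_oracle():
    return hand_rhs
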
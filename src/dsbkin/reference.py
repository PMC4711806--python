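"""Published joint-fit parameter estimates and worked-example conditions.

These are the reported best-fit parameter sets for the large yeast
(S. cerevisiae) DSB-rejoining datasets: sparsely-ionizing radiation
(30 MeV electrons at 7800 Gy/h, single and split doses, plus 60-Co
gamma-rays at ~33 Gy/h) fitted jointly, and densely-ionizing 3.5 MeV
alpha-particles (1400 Gy/h) fitted separately.  They serve as generating
parameters for synthetic datasets and as inputs for the worked-example
predictions.
"""

from __future__ import annotations

from .models import RDParams, TLKParams
from .protocols import (
    DENSELY_IONIZING,
    SPARSELY_IONIZING,
    ExposureProtocol,
)

__all__ = [
    "RD_SPARSE",
    "TLK_SPARSE",
    "RD_DENSE",
    "TLK_DENSE",
    "WORKED_EXAMPLES",
]

#: RD best fit, sparsely-ionizing joint dataset (k in Gy^-1, v in h^-1, q in Gy^-1).
RD_SPARSE = RDParams(k1=6.08e-2, k2=7.83e-3, k3=0.0, v1=1.07, v2=4.44e-2,
                     q1=1.22e-3, q2=2.67e-4)

#: TLK best fit, sparsely-ionizing joint dataset (fixation and interaction
#: rates all converged to zero).
TLK_SPARSE = TLKParams(c1=2.49e-2, c2=35.5e-3, c3=7.86e-3,
                       lambda1=1.32, lambda2=6.72e-2)

#: RD best fit, densely-ionizing (alpha-particle) dataset.
RD_DENSE = RDParams(k1=0.0, k2=0.145, k3=0.0, v1=0.0, v2=4.61e-2,
                    q1=0.0, q2=6.29e-4)

#: TLK best fit, densely-ionizing dataset.
TLK_DENSE = TLKParams(c1=0.0, c2=0.125, c3=19.7e-3, lambda1=0.0, lambda2=4.60e-2)

#: Worked-example exposure conditions with the reported mean observed
#: DSBs/cell: (radiation class, protocol, observed mean).
WORKED_EXAMPLES = [
    (SPARSELY_IONIZING, ExposureProtocol.single_dose(2400.0, 7800.0, 72.0), 30.2),
    (SPARSELY_IONIZING, ExposureProtocol.single_dose(1650.0, 33.0, 22.0), 5.6),
    (DENSELY_IONIZING, ExposureProtocol.single_dose(600.0, 1400.0, 72.0), 20.1),
]
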
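"""Fit the ex-Gaussian response-time model to simulated attention-task data.

Draws correct-response times from a known ex-Gaussian distribution (the
shape typical of visual attention tasks: a fast rise and a long right
tail), fits it by maximum likelihood, and prints the recovered parameters.
The fitted mu is the processing-speed outcome carried into the
longitudinal analysis.
"""

import numpy as np

from audcog import ExGaussParams, fit_exgauss, sample_exgauss

truth = ExGaussParams(mu=350.0, sigma=40.0, tau=120.0)
rng = np.random.default_rng(11)
rts = sample_exgauss(2000, truth, rng)

fit = fit_exgauss(rts)
p = fit.params
print(f"true parameters   : mu=350.0  sigma=40.0  tau=120.0 (ms)")
print(f"fitted parameters : mu={p.mu:.1f}  sigma={p.sigma:.1f}  "
      f"tau={p.tau:.1f} (ms)")
print(f"distribution mean : fitted {p.mean:.1f} vs sample "
      f"{np.mean(rts):.1f} ms")
print(f"log-likelihood {fit.loglik:.1f}, converged={fit.converged}")
print("\nmu+tau tracks the plain mean RT, while mu isolates the Gaussian "
      "component: a cleaner index of central processing speed than the "
      "skewed raw mean.")
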
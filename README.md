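# crowdkin

Kinetic analysis of enzymes that depolymerize **solid** substrates — PET
hydrolases such as IsPETase are the motivating case — for enzymologists and
enzyme engineers who see the *inhibition effect*: productivity rises with
enzyme loading, peaks, and then falls as the surface crowds, which the
Michaelis–Menten family cannot represent.

## The model

Free enzyme adsorbs onto substrate surface sites in fast quasi-equilibrium
(K_a, nM⁻¹; site density Γ, nmol/cm²; surface concentration N₀, cm²/L), so
the adsorbed complex is the physical root of

    K_a (E_T − [EN]) (Γ N₀ − [EN]) = [EN].

Adsorbed enzymes partition between an uncrowded state (catalytic constant
k_cat,uc) and a crowded, slower state (k_cat,c ≤ k_cat,uc) according to the
site coverage θ = [EN]/(Γ N₀) and a crowding equilibrium constant K_c:

    dP/dt = k_app(θ)·[EN],
    k_app(θ) = k_cat,uc (1 − θ + c K_c θ) / (K_c θ + 1 − θ),  c = k_cat,c/k_cat,uc.

Five constants (K_a, Γ, K_c, k_cat,uc, k_cat,c) describe a variant. They are
estimated in two steps: maximum likelihood on adsorption (solution-depletion)
data for (K_a, Γ), then maximum a posteriori on the initial-rate surface for
all five, with the step-1 estimates as a log-space Gaussian prior and the
adsorption capacity as an upper bound on Γ. Model adequacy is judged by BIC
against the inverse Michaelis–Menten law (saturating in enzyme, no
inhibition). The package also includes the surface-geometry toolkit used to
argue that crowding is physically plausible: adsorbed-amount → areal density
→ separation-distance conversions, Poisson point-pattern Monte Carlo, and
quadrant analysis of single-molecule localization tables.

Everything is driven by synthetic data generators that emulate the reference
study designs, so the full analysis is testable offline.

## Worked example

```python
import numpy as np
from crowdkin import (REFERENCE_PARAMETER_SETS, ReactionCondition,
                      degradation_rate, fit_adsorption, fit_kinetics,
                      optimal_loading)
from crowdkin.params import DEFAULT_ET_GRID
from crowdkin.simulate import (SimulationConfig, generate_adsorption,
                               generate_kinetics)

wt = REFERENCE_PARAMETER_SETS["30C"]["WT"]

# forward model at one condition
st = degradation_rate(wt, ReactionCondition(E_T=400, N_0=500))
print(f"EN={st.EN:.2f} nM  theta={st.theta:.3f}  rate={st.rate:.3f} mA260/min")
# EN=13.36 nM  theta=0.918  rate=1.255 mA260/min

# synthetic study at 5% replicate noise, then the two-step fit
kin = generate_kinetics(SimulationConfig(params=wt, cv=0.05, seed=42))
ads = generate_adsorption(wt, DEFAULT_ET_GRID["30C"], 500.0, cv=0.05, seed=43)
step1 = fit_adsorption(ads, n_starts=8, seed=0)
step2 = fit_kinetics(kin, prior=step1.flags["prior"],
                     gamma_upper=step1.flags["gamma_upper"], n_starts=16, seed=0)
print(step2.summary()["parameters"])
# {'K_a': 0.03003, 'Gamma': 0.02829, 'K_c': 0.87253,
#  'k_cat_uc': 0.45198, 'k_cat_c': 0.05980}

opt = optimal_loading(wt, 500.0, np.linspace(10, 600, 60))
print(f"optimal loading E_T*={opt.E_T_star:.1f} nM, rate={opt.rate_max:.3f}")
# optimal loading E_T*=57.2 nM, rate=1.959
```

Reading the output: at 400 nM total enzyme the surface is 92% covered, so
the mean per-enzyme rate k_app has collapsed toward k_cat,c and productivity
(1.255 mA260/min) sits well below the optimum (1.959 mA260/min at 57 nM) —
the inhibition effect. The two-step fit recovers the generating constants
(K_a = 0.0290, Γ = 0.0291, K_c = 0.890, k_cat,uc = 0.445, k_cat,c = 0.0588)
to within a few percent from data with 5% replicate noise.

The same workflow is scriptable from the shell:

```bash
crowdkin simulate-kinetics --variant WT --cv 0.05 --seed 42 --out kin.csv
crowdkin simulate-adsorption --variant WT --cv 0.05 --seed 43 --out ads.csv
crowdkin fit-adsorption ads.csv --n0 500 --out ads_fit.json
crowdkin fit-kinetics kin.csv --prior-json ads_fit.json --out kin_fit.json
crowdkin geometry density --pmol 4        # separation distances on the film
crowdkin run config.yaml --outdir results # full pipeline from a YAML config
```

See `docs/methods.md` for the model assumptions, estimation details,
numerical choices, and limitations.

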
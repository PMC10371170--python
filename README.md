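# chargebem

Charge-based boundary element solver for the electric field that
transcranial magnetic stimulation (TMS) induces in a layered volume
conductor. It is aimed at computational neurostimulation work: given
nested triangulated conductivity interfaces (an STL-based head model) and
a coil described by elementary current elements, it computes the induced
surface charge density and from it the total E-field anywhere in the
head — with both an iterative solver and a factor-once/solve-many direct
solver for scanning many coil positions against one head model.

## The model

Under the quasistatic approximation the total field is the coil's primary
field plus the Coulomb field of charges induced on each conductivity
interface *S*:

    E(r) = E_p(r) + (1/4πε₀) ∫_S ρ(r′) (r−r′)/|r−r′|³ dS′

Current conservation across the interfaces, σ_in n·E_in = σ_out n·E_out,
turns this into a well-conditioned Fredholm equation of the second kind
for the scaled charge density ρ* = ρ/ε₀:

    ρ*(r)/2 − K n·∫_S (r−r′)/(4π|r−r′|³) ρ*(r′) dS′ = K n·E_p(r),

where K = (σ_in−σ_out)/(σ_in+σ_out) is the conductivity contrast. With
piecewise-constant charges per facet this becomes an N×N system A x = b,
with the diagonal exactly ½ and near-facet interactions evaluated by
closed-form triangle integrals. Two solution paths share the same
operator:

* **iterative** — unrestarted GMRES, which converges in a few tens of
  iterations to a 1e-6 relative residual;
* **direct** — one pivoted LU factorization per head model, after which
  every additional coil pose costs only a pair of triangular solves.

A synthetic-data module generates multilayer concentric-sphere head
models and figure-8 coils, plus analytic oracles (uniform-field sphere,
conductivity-profile independence, refined-mesh self-convergence), so the
whole test suite runs without any external head data.

## Worked example

Three-layer sphere head (radii 90/85/80 mm, conductivities 0.33/0.01/0.33
S/m, 1280 facets per surface) with a figure-8 coil 5 mm above the vertex,
dI/dt = 9.4e7 A/s:

```python
import numpy as np
from chargebem import (
    assemble_dense, assemble_rhs, error_total, factorize,
    field_off_surface, roi_select, solve_direct, solve_iterative,
)
from chargebem.sphere_oracle import default_three_layer_case

model, probes, coil = default_three_layer_case()
op = assemble_dense(model)
b = assemble_rhs(model, coil)

sol_gmres, report = solve_iterative(op, b, tol=1e-6)
print(f"GMRES: {report.iterations} iterations, residual {report.residual:.2e}")

fact = factorize(op)
(sol_lu,) = solve_direct(fact, b, model.fingerprint())

E_gmres = field_off_surface(model, sol_gmres, coil, probes).e_total
E_lu = field_off_surface(model, sol_lu, coil, probes).e_total

roi_center = probes[np.argmin(np.linalg.norm(
    probes - coil.elements.mean(axis=0), axis=1))]
roi = roi_select(probes, roi_center, diameter=0.04)

print(f"peak |E| on probe shell: {np.linalg.norm(E_gmres, axis=1).max():.1f} V/m")
print(f"direct vs iterative Error_total: "
      f"{100*error_total(E_lu, E_gmres):.5f}% (all {len(probes)} probes), "
      f"{100*error_total(E_lu[roi], E_gmres[roi]):.5f}% ({len(roi)}-probe ROI)")
```

prints

```
GMRES: 30 iterations, residual 4.87e-07
peak |E| on probe shell: 10.8 V/m
direct vs iterative Error_total: 0.00002% (all 1000 probes), 0.00000% (25-probe ROI)
```

The probe shell sits at 0.8 × the innermost radius; 10.8 V/m is the peak
induced field there for a motor-threshold-like pulse. The two solution
paths agree far below either one's discretization error, which is the
point of the direct path: factor once, then sweep coil poses at
triangular-solve cost.

The same workflow is available from the shell:

```
chargebem make-sphere --out-dir model/
chargebem make-coil --center 0,0,0.095 --out coil.txt
chargebem factorize --model model/model.json --out fact.h5
chargebem solve --model model/model.json --coil coil.txt \
    --factorization fact.h5 --out rho.txt
chargebem evaluate --model model/model.json --coil coil.txt \
    --charges rho.txt --points model/probes.txt --out field.tsv
chargebem compare field_a.tsv field_b.tsv --roi-center 0,0,0.064 --roi-diameter 0.04
```

or end-to-end with a JSON/TOML config via `chargebem run config.json`
(multiple poses per run; direct mode factorizes once across all of them).

See `docs/methods.md` for the discretization, solver and oracle details.

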
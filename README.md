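# retrochannel

Tools for quantifying how **retroactivity** — the load that downstream
binding sites exert on the signaling circuit that drives them — limits
information transmission through enzymatic signaling circuits.

When a circuit's output protein Z is sequestered by the DNA sites it is
meant to regulate, the upstream system feels that load, and the circuit's
ability to convey which input symbol was transmitted degrades. This package
makes that statement quantitative for five circuit topologies that mirror
standard communication-channel models (SISO, broadcast, MIMO, loaded MIMO,
multiple access), in two regimes:

* **Low molecular counts** — the stationary chemical master equation (CME)
  is solved exactly over the enumerated microstates. With a binary
  concentration on-off-keying alphabet (I(t0) ∈ {0, 1}) the input/output
  pair (I₁(t0), 1{Z₁(ts) ≥ 1}) is a **Z-channel**: symbol 0 is received
  noiselessly, symbol 1 is erased with probability

  A = P(Z₁(ts) = 0 | I₁(t0) = 1),

  so the mutual information is I = H(X) − H(X|Y) of the joint
  [[P01, 0], [A·P11, (1−A)·P11]] (nats). Closed forms for A exist per
  topology in the fast-binding regime k0± ≫ c, e.g.
  A₀ = (1+k₀)c₂ / (c₁ + (1+k₀)c₂) for the isolated circuit and
  A_N = 1 − c₁ / [(1+k₀)c₂ + (1 + Σⱼ 1/k₃ⱼ)c₁] with N downstream sites;
  larger A means worse transmission, and A grows with the load.

* **High molecular counts** — the linear noise approximation (LNA):
  deterministic steady states from the rate equations, Gaussian
  fluctuations from the stationary Lyapunov equation, and the resulting
  additive-Gaussian-channel capacity ½·ln(1 + σ²_signal/σ²_noise).

The package also carries its own independent oracles: a Gillespie
stochastic-simulation engine for validating stationary CME solutions, a
Blahut–Arimoto capacity solver, and a dual (KL-divergence) capacity upper
bound whose minimum coincides with the Z-channel capacity.

## Worked example

How does the broadcast load N reshape the channel, at fast binding
(k0± = k3± = 100, c₁ = c₂ = 1, unit dissociation constants, unit totals)?

```python
from retrochannel import build_model, RateParameters, a_hat, mi_from_cme, z_channel_capacity
from retrochannel.constants import a0, aN

for n in (0, 1, 2, 4):
    rates = RateParameters.uniform(100.0, 100.0, 1.0, 1.0, 100.0, 100.0, n_sites=n)
    topo = "SISO_N_DOWNSTREAM" if n else "ISOLATED_SISO"
    model = build_model(topo, rates, n_downstream=n)
    a = a_hat(model)
    closed = aN(rates.k0, rates.c1, rates.c2, rates.k3).value if n else a0(rates.k0, rates.c1, rates.c2).value
    print(f"N={n}:  A_cme={a:.4f}  A_closed={closed:.4f}  "
          f"MI={mi_from_cme(model):.4f} nats  capacity={z_channel_capacity(a):.4f} nats")
```

prints

```
N=0:  A_cme=0.6678  A_closed=0.6667  MI=0.1318 nats  capacity=0.1376 nats
N=1:  A_cme=0.7506  A_closed=0.7500  MI=0.0953 nats  capacity=0.1000 nats
N=2:  A_cme=0.8004  A_closed=0.8000  MI=0.0747 nats  capacity=0.0786 nats
N=4:  A_cme=0.8573  A_closed=0.8571  MI=0.0522 nats  capacity=0.0550 nats
```

Each added site raises the erasure probability A (the exact CME value and
the closed form agree to ~1e-3 at this binding speed) and drains mutual
information and capacity: retroactivity is a communication cost. A second
independent upstream system that captures some of the sites (the
multiple-access topology) interpolates A between the isolated and fully
loaded values, mitigating that cost.

## Command line

```
retrochannel mi-vs-load        # A, MI, capacity vs load N and MAC split Q
retrochannel mimo-mitigation   # does a second branch help? (G vs AN test)
retrochannel capacity-bounds   # bound surface + capacity curve over (A, P01)
retrochannel lna               # high-count means/variances/AWGN capacities
retrochannel generate          # seeded synthetic rate draws
retrochannel validate          # CME vs closed-form consistency battery
```

Every subcommand writes CSV tables and a `manifest.json` (config hash,
seed, version) so runs are reproducible bit for bit.

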
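# sugarglass

Hydrogen-bond network analysis for trehalose–water glasses at low water
content.

Dry preservation stores cells and biomolecules in a vitrified sugar
matrix, and the outcome hinges on the final water content: dry too
little and molecular mobility stays high, dry too much and the matrix
rigidifies into an interconnected sugar skeleton that damages the
embedded material. `sugarglass` implements the analysis pipeline used to
characterize this transition from molecular configurations — it is aimed
at people studying amorphous sugar matrices (lyoprotection,
glass-forming mixtures, anhydrobiosis) who have trajectories from an MD
engine, or who want fully synthetic systems with known ground truth.

## What it computes

**Hydrogen bonds.** A donor O–H···acceptor O contact is a hydrogen bond
when the O–O minimum-image distance satisfies d(O···O) ≤ 3.5 Å and the
O-H···O angle at the hydrogen exceeds 150°. Detection runs under
periodic (orthorhombic) boundaries with a cell-list implementation that
is exactly equivalent to the brute-force reference. Bonds are classed
t-t (sugar–sugar), t-w (sugar donates to water), w-t (water donates to
sugar) and w-w.

**Network statistics.** Per frame: the stoichiometry
N_HB/N_t — bonds per *participating* molecule — for each class;
participation percentages; n-body sugar clusters (connected components
over direct-or-indirect t-t bonds); the bound/free water partition
(bound ⇔ at least one H-bond to sugar). Frames are analyzed
independently and reported as mean ± sample standard deviation.

**Dynamics.** Time-origin-averaged mean squared displacement of named
atom selections (e.g. all `O16`), the Einstein-relation diffusion
coefficient D = slope/6 (Å²/ps → m²/s via 1 Å²/ps = 10⁻⁸ m²/s), and
radial distribution functions g(r) with first-minimum extraction.

**Curve fits.** Three models in the Gordon–Taylor family:

* glass transition of the binary mixture,
  `Tg(x_t) = (x_t·Tg_t + k1·(1−x_t)·Tg_w) / (x_t + k1·(1−x_t))`,
  with x_t the trehalose mass fraction and k1 fitted;
* the same functional form reused for the t-t H-bond stoichiometry,
  `N(x_t) = (x_t·N_pure + k2·(1−x_t)·N_inf) / (x_t + k2·(1−x_t))`,
  with the dry-glass value N_pure fixed and (k2, N_inf) fitted;
* a four-parameter Gaussian `y = y0 + A·exp(−(x−xc)²/(2w²))` for
  normalized post-rehydration viability versus water content, from
  which EC50 (the 0.5 crossing on the low-water branch) is extracted.

Water content R (gH₂O/gdw, grams of water per gram of dry weight) and
mass fraction are linked by x_t = 1/(1+R); the `composition` module
converts both to and from molecule counts.

## Worked example

Build a small planted network — 8 sugar molecules with a 4-molecule
chain, a 2-molecule cluster and two singletons, plus 6 waters of which 3
donate to sugars — and run the frame statistics:

```python
import sugarglass as sg
from sugarglass.synthetic import PlantedNetworkSpec, generate_planted_network
from sugarglass.trajio import Box

spec = PlantedNetworkSpec(
    n_trehalose=8, n_water=6,
    tt_edges=((0, 1), (1, 2), (2, 3), (4, 5)),
    wt_edges=((8, 0), (9, 4), (10, 6)),
    box=Box(60, 60, 60), seed=0,
)
net = generate_planted_network(spec)
bonds = sg.detect_hbonds(net.frame, net.topology)

c = sg.census(bonds, net.topology)
print("n_tt:", c.n_tt, " ratio_tt:", round(c.ratio_tt, 4))
cl = sg.trehalose_clusters(bonds, net.topology)
print("clusters:", dict(sorted(cl.counts.items())))
wp = sg.water_partition(bonds, net.topology)
print("bound/free:", wp.n_bound, wp.n_free)
```

prints

```
n_tt: 4  ratio_tt: 0.6667
clusters: {1: 2, 2: 1, 4: 1}
bound/free: 3 3
```

i.e. 4 sugar–sugar bonds shared by 6 participating molecules
(4/6 ≈ 0.667 bonds per participant), a cluster-size histogram with one
4-body and one 2-body cluster plus two singletons, and half of the
waters bound to sugar. The detector is guaranteed to return exactly the
planted adjacency, so every downstream number has a hand-checkable
truth.

The same operations are available from the shell:

```sh
sugarglass composition --n-trehalose 216 --content 2.0   # -> 8209 waters
sugarglass hbonds --traj frames.pdb --topology top.tsv
sugarglass network-stats --traj frames.pdb --topology top.tsv --per-frame
sugarglass msd --traj traj.xyz --topology top.tsv --select O16
sugarglass fit-hbond --data stoich.tsv --n-pure 3.77 --x-is-content
sugarglass run-pipeline --config run.yaml --out report/
```

## Layout

```
src/sugarglass/
  topology.py    atom records, sidecar I/O, name-convention inference
  trajio.py      Box/Frame/Trajectory, PDB and extended-XYZ round trips
  hbond.py       minimum image, geometric criterion, cell-list detector
  network.py     census, clusters, water partition, frame averaging
  dynamics.py    unwrap, MSD, diffusion, RDF, first minimum
  fitting.py     Gordon-Taylor family fits, viability Gaussian, EC50
  composition.py counts <-> water content <-> mass fraction
  synthetic.py   planted networks, random walks, ideal gas, curve data
  pipeline.py    end-to-end report bundle
  cli.py         `sugarglass` command
```

See `docs/methods.md` for the model conventions, numerical choices and
known limitations.
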
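# sarudango

An individual-based model of huddling in Japanese macaques (*Macaca
fuscata*), together with the full simulation experiment built around it:
a factorial parameter sweep, negative-binomial regression of the outcomes,
and ranking of simulated temperature–cluster-size lines against four field
sites.

Japanese macaques huddle against the cold, and the size of those huddles
varies enormously between sites: typical troops form huddles of two to five
animals, while on Shodoshima Island "sarudango" (monkey dumplings) of more
than fifty — sometimes over a hundred — individuals form in winter.  The
question the model addresses is whether such differences can emerge from
simple individual join/leave decisions rather than site-specific ecology.

## The model

N identical agents live on a 16 × 16 toroidal grid.  Lone agents
random-walk one patch per tick; agents in a huddle are stationary.  Each
tick, in shuffled order, a lone agent senses everyone within 2 patches,
draws one in-range agent uniformly, and joins its cluster with probability

    p_join = (n_ci / N) · (1/T)             existing huddle of size n_ci
    p_join = (n_lone / N) · (1/T) · (1/J²)  nucleation (lone partner)

where T ∈ {1..10} is the temperature scale (1 = coldest), J the joining
threshold (the agents' selectivity about founding a new huddle; both
founders of a pair apply it), and n_lone the current number of unhuddled
agents.  A huddled agent in a cluster of size n_ci leaves with

    p_leave = ((N − n_ci) / N) · (1/L)

per tick, L ≥ 10 the leaving threshold; a full-group huddle is absorbing.
A run ends when every agent is huddled or after 20,000 ticks.  See
`docs/methods.md` for the full rule set and the reasoning behind the
selectivity placement.

## A worked example

```python
from sarudango import SimParams, run_simulation

rec = run_simulation(SimParams(group_size=160, temperature=1,
                               join_threshold=6, leave_threshold=90), seed=1)
print(rec.termination, rec.steps_elapsed)
print(rec.n_clusters, rec.cluster_sizes)
```

prints

```
all_joined 2089
3 (111, 46, 3)
```

— at the coldest temperature a selective population (J = 6) condenses into
a few large huddles within ~2,100 ticks: the whole group of 160 ends up in
three clusters, the largest of 111 animals, the kind of giant huddle
reported only from Shodoshima.  The same settings at temperature 10 run to
the 20,000-tick cap with nothing but transient pairs and triples.

The sweep, regression and site-comparison stages run from the command line:

```
sarudango all --seed 0 --reps 2 --group-sizes 70,160 --out results/ -v
```

writes `sweep.csv`, per-combination summaries, GLM coefficient tables with
95% intervals, VIFs, fitted temperature lines, site rankings and a
`manifest.json` of content hashes (identical config + seed ⇒ identical
hashes).

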
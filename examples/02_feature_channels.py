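"""Build the four heterogeneous feature channels for a drug universe.

DDI: spectral embedding U*sqrt(S) of the interaction graph (25 leading
components). ATC: Tanimoto similarity of first-level code sets, used as a
pairwise score. DTI/SE: binary profiles compressed to 25 principal
components.
"""

from combifuse import (
    PCAConfig,
    SVDEmbeddingConfig,
    atc_similarity,
    binary_profiles,
    ddi_embedding,
    generate,
    reduce_pca,
)

universe, network, _ = generate(seed=1)

emb = ddi_embedding(network, SVDEmbeddingConfig(n_keep=25))
print(f"DDI embedding:   {emb.values.shape}  (drugs x components)")

sim = atc_similarity(universe)
print(f"ATC similarity:  {sim.values.shape}, values in [{sim.values.min():.2f}, {sim.values.max():.2f}]")

for channel in ("dti", "se"):
    raw = binary_profiles(universe, channel)
    red = reduce_pca(raw, PCAConfig(n_components=25))
    print(f"{channel.upper()} profiles:    {raw.values.shape} -> PCA {red.values.shape}")

# The classic worked example: a drug with first-level codes {A} against one
# with {A, C, D, H, R, S} shares 1 of 6 distinct codes -> similarity 1/6.
a, b = {"A"}, {"A", "C", "D", "H", "R", "S"}
print(f"Tanimoto({a}, B) = {len(a & b)}/{len(a | b)} = {len(a & b)/len(a | b):.4f}")
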
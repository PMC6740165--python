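"""The character scheme shared by the vectorizer and registry validation."""

# 29 features: the lowercase alphabet plus the three specials '-', '_', '+'.
# Digits, whitespace and all other punctuation carry no weight.
SCHEME = "abcdefghijklmnopqrstuvwxyz-_+"
SCHEME_INDEX = {ch: i for i, ch in enumerate(SCHEME)}
N_FEATURES = len(SCHEME)
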
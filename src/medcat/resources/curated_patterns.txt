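X is a Y
X are Y
X and other Y
X as a Y
X such as Y
X is an Y
X as an Y
X is an important Y
X a new Y
X are the most common Y
X is a rare Y
X is a novel Y
X is a major Y
X is an essential Y
X was the only Y
X was the most common Y
X is a common Y
X is a new Y
X is a complex Y
X is an effective Y
X is a potent Y
X is the most common Y
X are rare Y
X is a widely used Y
X is an uncommon Y
X is an autosomal dominant Y
X is a form of Y
X is one of the major Y
X is a chronic Y
X and other forms of Y
X is a broad spectrum Y
X is the primary Y
X is a rare autosomal recessive Y
X is the most common type of Y
X is the second most common Y
X are the most frequent Y
X is the most widely used Y
X is the most frequent Y
X is the most common primary Y
X is one of the major Y
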
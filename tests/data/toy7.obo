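format-version: 1.2
ontology: synthetic

[Term]
id: GO:0000001
name: toy term 1
namespace: synthetic_function

[Term]
id: GO:0000002
name: toy term 2
namespace: synthetic_function
is_a: GO:0000001 ! toy term 1

[Term]
id: GO:0000003
name: toy term 3
namespace: synthetic_function
is_a: GO:0000001 ! toy term 1

[Term]
id: GO:0000004
name: toy term 4
namespace: synthetic_function
is_a: GO:0000002 ! toy term 2
is_a: GO:0000003 ! toy term 3

[Term]
id: GO:0000005
name: toy term 5
namespace: synthetic_function
is_a: GO:0000002 ! toy term 2

[Term]
id: GO:0000006
name: toy term 6
namespace: synthetic_function
is_a: GO:0000005 ! toy term 5

[Term]
id: GO:0000007
name: toy term 7
namespace: synthetic_function
is_a: GO:0000004 ! toy term 4
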
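"""Compress an n-gram transition graph by pruning rare transitions.

The state "how" continues five ways with relative frequencies 40/30/20/6/4
percent; the state "how many" continues four ways at 45/35/12/8 percent.
Dropping transitions below a conditional-probability threshold shrinks the
transition freedom (out-degree) of each state — and with it the cost of
storing the model and of weighing options during inference.
"""

from socev import TransitionGraph, prune_graph, total_transition_freedom, transition_freedom

graph = TransitionGraph()
for target, count in zip(["to", "do", "many", "much", "come"], [40, 30, 20, 6, 4]):
    graph.add_transition("how", target, count)
for target, count in zip(["people", "times", "days", "years"], [45, 35, 12, 8]):
    graph.add_transition("many", target, count)

print(f"total transition freedom before: {total_transition_freedom(graph)}")
pruned = prune_graph(graph, prob_threshold=0.10)
pruned_child = prune_graph(graph, prob_threshold=0.15)
print(f"TF('how')  at threshold 0.10: {transition_freedom(graph, 'how')} -> "
      f"{transition_freedom(pruned, 'how')}")
print(f"TF('many') at threshold 0.15: {transition_freedom(graph, 'many')} -> "
      f"{transition_freedom(pruned_child, 'many')}")
print(f"states flagged unreachable at 0.10: {sorted(pruned.flagged)}")
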
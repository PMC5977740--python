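{
  "version": "1.0",
  "comment": "Default healthfulness rule set. Product rules are ordered keyword patterns matched case-insensitively against 'name + category hint'; first match wins. Edit or replace via ClassificationRuleSet.from_json.",
  "product_rules": [
    ["chocolate milk", "less_healthy"],
    ["flavoured milk", "less_healthy"],
    ["diet soft drink", "least_healthy"],
    ["soft drink", "least_healthy"],
    ["cola", "least_healthy"],
    ["soda", "least_healthy"],
    ["energy drink", "least_healthy"],
    ["sports drink", "least_healthy"],
    ["slushie", "least_healthy"],
    ["slush", "least_healthy"],
    ["candy", "least_healthy"],
    ["chocolate", "least_healthy"],
    ["chips", "least_healthy"],
    ["ice cream", "least_healthy"],
    ["frozen treat", "least_healthy"],
    ["donut", "least_healthy"],
    ["doughnut", "least_healthy"],
    ["fries", "least_healthy"],
    ["poutine", "least_healthy"],
    ["hot dog", "least_healthy"],
    ["burger", "least_healthy"],
    ["pizza", "least_healthy"],
    ["fried chicken", "least_healthy"],
    ["nachos", "least_healthy"],
    ["granola", "less_healthy"],
    ["muffin", "less_healthy"],
    ["juice", "less_healthy"],
    ["smoothie", "less_healthy"],
    ["cheese", "less_healthy"],
    ["crackers", "less_healthy"],
    ["sandwich", "less_healthy"],
    ["coffee", "less_healthy"],
    ["wrap", "less_healthy"],
    ["yogurt", "less_healthy"],
    ["sparkling water", "most_healthy"],
    ["water", "most_healthy"],
    ["milk", "most_healthy"],
    ["fruit", "most_healthy"],
    ["vegetable", "most_healthy"],
    ["apple", "most_healthy"],
    ["banana", "most_healthy"],
    ["salad", "most_healthy"],
    ["egg", "most_healthy"]
  ],
  "retailer_rules": [
    ["prepared grocery", "less_healthy"],
    ["grocery", "most_healthy"],
    ["farmers market", "most_healthy"],
    ["farmers' market", "most_healthy"],
    ["salad bar", "most_healthy"],
    ["sandwich outlet", "most_healthy"],
    ["sandwich", "most_healthy"],
    ["smoothie", "most_healthy"],
    ["sit-down restaurant", "less_healthy"],
    ["restaurant", "less_healthy"],
    ["cafeteria", "less_healthy"],
    ["coffee", "less_healthy"],
    ["supplement", "less_healthy"],
    ["pizza", "least_healthy"],
    ["burger", "least_healthy"],
    ["taco", "least_healthy"],
    ["fried chicken", "least_healthy"],
    ["asian", "least_healthy"],
    ["ice cream", "least_healthy"],
    ["pub", "least_healthy"],
    ["lounge", "least_healthy"],
    ["alcohol", "least_healthy"],
    ["fast food", "least_healthy"]
  ],
  "brand_map": {
    "coca-cola": "cola soft drink",
    "coke": "cola soft drink",
    "pepsi": "cola soft drink",
    "sprite": "soft drink",
    "aquafina": "bottled water",
    "dasani": "bottled water",
    "gatorade": "sports drink",
    "powerade": "sports drink",
    "red bull": "energy drink",
    "monster": "energy drink",
    "lays": "potato chips",
    "doritos": "corn chips",
    "nestle": "chocolate bar",
    "cadbury": "chocolate bar",
    "tropicana": "fruit juice",
    "minute maid": "fruit juice",
    "dairyland": "milk"
  },
  "child_tags": [
    "cartoon_character",
    "animated_character",
    "fictional_character",
    "licensed_character",
    "taste_appeal",
    "humour",
    "action_adventure",
    "fantasy",
    "fun_shapes_colours",
    "contest",
    "giveaway",
    "cartoonish_font",
    "child_actor"
  ],
  "sports_tags": [
    "physical_activity_reference",
    "exercise_reference",
    "sport_reference",
    "game_reference",
    "recreation_reference",
    "performance_reference",
    "competition_reference"
  ],
  "pricing_overeating_ids": [1, 2, 3, 4],
  "pricing_comparison_ids": [5, 6, 7, 8, 9, 10, 11],
  "item_labels": {}
}
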